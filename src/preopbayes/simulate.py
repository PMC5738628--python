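"""Synthetic claims-cohort generator.

The source database for this analysis is a proprietary nationwide insurance
claims collection, so nothing can be deposited; this module generates
cohorts with the statistical structure the analysis assumes, making every
downstream stage testable.  The generative model is exactly the model the
inference targets: surgeries are clustered in institutions, each
institution carries a normal random intercept c ~ N(0, sigma0_sq) on the
log-odds scale, binary patient covariates are drawn independently with
configured marginals, and the latent test-ordering event occurs with
probability logistic(beta0 + sum_k beta_k x_k + c).  When the event occurs,
at least one of the four blood-test types receives an order date inside the
preoperative window; otherwise any generated order dates fall outside it,
so the window rule recovers the latent outcome exactly.

Default dimensions and marginals follow the published cohort: 69,252
surgeries across 9,922 institutions, 57.0% female, 69.0% outpatient, 40.6%
of surgeries at institutions with >=100 beds, overall testing prevalence
59.0%.  Default effects are the published adjusted odds ratios (log scale).
The intercept defaults to an auto-calibrated value that makes the expected
prevalence hit the configured target (0.59) under the configured effects.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .cohort import TEST_DATE_COLUMNS
from .exceptions import ConfigurationError

__all__ = ["SyntheticConfig", "generate_institutions", "generate_cohort", "write_truth"]

STUDY_START = np.datetime64("2012-04-01")
STUDY_END = np.datetime64("2016-03-31")

# Per-surgery marginals of the default binary covariates (published
# descriptive table).  Mutually exclusive categories (anesthesia type) are
# approximated as independent flags; only marginals are published and
# covariate correlation is an explicit non-goal.
DEFAULT_MARGINALS = {
    "female": 0.570,
    "outpatient": 0.690,
    "antiplatelet": 0.025,
    "anticoagulant": 0.005,
    "acei_arb": 0.078,
    "diuretic": 0.016,
    "chemotherapy": 0.011,
    "general_anesthesia": 0.127,
    "regional_anesthesia": 0.105,
}

# Published adjusted odds ratios, log scale.  beds_ge_100 and teaching are
# institution-level and enter through the institution table.
DEFAULT_TRUE_BETA = {
    "female": math.log(1.03),
    "outpatient": math.log(0.37),
    "antiplatelet": math.log(1.40),
    "anticoagulant": math.log(3.57),
    "acei_arb": math.log(1.53),
    "diuretic": math.log(1.40),
    "chemotherapy": math.log(1.55),
    "general_anesthesia": math.log(5.42),
    "regional_anesthesia": math.log(3.14),
    "beds_ge_100": math.log(2.64),
    "teaching": math.log(0.71),
}

# Probability that each test type is ordered, conditional on the latent
# testing event (published per-test prevalences / overall prevalence).
DEFAULT_TEST_PROBS = {
    "cbc_date": 0.578 / 0.590,
    "metabolic_panel_date": 0.496 / 0.590,
    "lft_date": 0.480 / 0.590,
    "coagulation_date": 0.356 / 0.590,
}

# Per-surgery age-band shares of the published cohort; ages drawn uniformly
# within the band.
AGE_BANDS = [((20, 24), 0.044), ((25, 34), 0.190), ((35, 44), 0.286),
             ((45, 54), 0.264), ((55, 64), 0.216)]

TEACHING_PROB = 0.078


@dataclass
class SyntheticConfig:
    """Generative parameters for a synthetic claims cohort.

    ``true_intercept=None`` requests calibration so that the expected
    outcome prevalence equals ``target_prevalence``.
    """

    n_patients: int = 69_252
    n_institutions: int = 9_922
    prop_large: float = 0.406
    institution_size_dispersion: float = 0.5
    covariate_marginals: dict = field(default_factory=lambda: dict(DEFAULT_MARGINALS))
    true_beta: dict = field(default_factory=lambda: dict(DEFAULT_TRUE_BETA))
    true_intercept: float | None = None
    target_prevalence: float = 0.590
    sigma0_sq: float = 1.0
    test_window_days: int = 60
    test_order_probs: dict = field(default_factory=lambda: dict(DEFAULT_TEST_PROBS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ConfigurationError(f"n_patients must be positive, got {self.n_patients}")
        if self.n_institutions <= 0:
            raise ConfigurationError(
                f"n_institutions must be positive, got {self.n_institutions}"
            )
        if self.n_institutions > self.n_patients:
            raise ConfigurationError(
                "n_institutions must not exceed n_patients "
                f"({self.n_institutions} > {self.n_patients})"
            )
        if not (0.0 <= self.prop_large <= 1.0):
            raise ConfigurationError(f"prop_large must lie in [0,1], got {self.prop_large}")
        if self.institution_size_dispersion <= 0:
            raise ConfigurationError(
                "institution_size_dispersion must be positive, got "
                f"{self.institution_size_dispersion}"
            )
        for name, p in self.covariate_marginals.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(
                    f"covariate_marginals[{name!r}] must lie in [0,1], got {p}"
                )
        for name, p in self.test_order_probs.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(
                    f"test_order_probs[{name!r}] must lie in [0,1], got {p}"
                )
        if self.sigma0_sq < 0:
            raise ConfigurationError(f"sigma0_sq must be >= 0, got {self.sigma0_sq}")
        if self.test_window_days <= 0:
            raise ConfigurationError(
                f"test_window_days must be positive, got {self.test_window_days}"
            )
        if not (0.0 < self.target_prevalence < 1.0):
            raise ConfigurationError(
                f"target_prevalence must lie in (0,1), got {self.target_prevalence}"
            )

    def resolved_intercept(self) -> float:
        if self.true_intercept is not None:
            return float(self.true_intercept)
        return _calibrate_intercept(self)


def _effect_marginals(config: SyntheticConfig) -> list[tuple[float, float]]:
    """(beta, marginal) pairs for every effect with a nonzero coefficient,
    including the institution-level flags."""
    marg = dict(config.covariate_marginals)
    marg.setdefault("beds_ge_100", config.prop_large)
    marg.setdefault("teaching", TEACHING_PROB)
    out = []
    for name, beta in config.true_beta.items():
        p = marg.get(name)
        if p is None:
            raise ConfigurationError(
                f"true_beta[{name!r}] has no matching covariate marginal"
            )
        if beta != 0.0:
            out.append((float(beta), float(p)))
    return out


def _calibrate_intercept(config: SyntheticConfig) -> float:
    """Solve E[logistic(beta0 + S + c)] = target for beta0.

    S enumerates the independent-covariate sum exactly when there are few
    effects (<= 16) and is Monte-Carlo approximated (fixed internal seed)
    otherwise; c is integrated by Gauss-Hermite quadrature.
    """
    effects = _effect_marginals(config)
    if len(effects) <= 16:
        vals = np.array([0.0])
        probs = np.array([1.0])
        for beta, p in effects:
            vals = np.concatenate([vals, vals + beta])
            probs = np.concatenate([probs * (1.0 - p), probs * p])
    else:
        rng = np.random.default_rng(123456789)
        draws = 200_000
        vals = np.zeros(draws)
        for beta, p in effects:
            vals += beta * (rng.random(draws) < p)
        probs = np.full(draws, 1.0 / draws)
    if config.sigma0_sq > 0:
        nodes, weights = np.polynomial.hermite_e.hermegauss(41)
        c_vals = nodes * math.sqrt(config.sigma0_sq)
        c_w = weights / weights.sum()
    else:
        c_vals = np.array([0.0])
        c_w = np.array([1.0])

    def prevalence(b0: float) -> float:
        eta = b0 + vals[:, None] + c_vals[None, :]
        return float(probs @ expit(eta) @ c_w)

    return brentq(lambda b0: prevalence(b0) - config.target_prevalence, -30.0, 30.0,
                  xtol=1e-10)


def generate_institutions(config: SyntheticConfig) -> pd.DataFrame:
    """Institution table: id, bed count, teaching flag, random intercept,
    and the Dirichlet allocation weight used to assign surgeries.

    A ``prop_large`` fraction of institutions gets >=100 beds; bed counts
    are log-uniform on [10, 99] and [100, 1000] (only the dichotomy matters
    downstream).  Random intercepts are i.i.d. N(0, sigma0_sq).  Allocation
    weights come from a symmetric Dirichlet with concentration
    ``institution_size_dispersion``: one knob for the right-skewed
    surgeries-per-institution distribution.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_institutions
    large = rng.random(m) < config.prop_large
    beds = np.where(
        large,
        np.round(np.exp(rng.uniform(math.log(100), math.log(1000), m))),
        np.round(np.exp(rng.uniform(math.log(10), math.log(99.49), m))),
    ).astype(int)
    beds = np.where(large, np.clip(beds, 100, None), np.clip(beds, 10, 99))
    teaching = rng.random(m) < TEACHING_PROB
    intercepts = (
        rng.standard_normal(m) * math.sqrt(config.sigma0_sq)
        if config.sigma0_sq > 0
        else np.zeros(m)
    )
    weights = rng.dirichlet(np.full(m, config.institution_size_dispersion))
    return pd.DataFrame(
        {
            "institution_id": np.arange(m),
            "beds": beds,
            "teaching": teaching,
            "random_intercept": intercepts,
            "allocation_weight": weights,
        }
    )


def generate_cohort(
    config: SyntheticConfig, institutions: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Generate a raw claims table (one row per surgery).

    Deterministic given the config (the institution stream and the cohort
    stream are both derived from ``config.seed``), so identical configs
    produce bit-identical tables.
    """
    if institutions is None:
        institutions = generate_institutions(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = config.n_patients

    inst_idx = rng.choice(
        len(institutions), size=n, p=institutions["allocation_weight"].to_numpy()
    )
    beds = institutions["beds"].to_numpy()[inst_idx]
    teaching = institutions["teaching"].to_numpy()[inst_idx]
    c = institutions["random_intercept"].to_numpy()[inst_idx]

    band_idx = rng.choice(len(AGE_BANDS), size=n, p=[w for _, w in AGE_BANDS])
    lo = np.array([b[0][0] for b in AGE_BANDS])[band_idx]
    hi = np.array([b[0][1] for b in AGE_BANDS])[band_idx]
    age = rng.integers(lo, hi + 1)

    cov = {}
    for name, p in config.covariate_marginals.items():
        cov[name] = rng.random(n) < p
    cov["beds_ge_100"] = beds >= 100
    cov["teaching"] = teaching

    beta0 = config.resolved_intercept()
    eta = np.full(n, beta0) + c
    for name, beta in config.true_beta.items():
        if name not in cov:
            raise ConfigurationError(
                f"true_beta[{name!r}] has no matching covariate marginal"
            )
        eta += beta * cov[name]
    outcome = rng.random(n) < expit(eta)

    n_days = int((STUDY_END - STUDY_START) / np.timedelta64(1, "D")) + 1
    surgery = STUDY_START + rng.integers(0, n_days, n).astype("timedelta64[D]")

    raw = pd.DataFrame(
        {
            "patient_id": np.arange(n),
            "age": age,
            "sex": np.where(cov["female"], "F", "M")
            if "female" in cov
            else np.full(n, "U"),
            "institution_id": institutions["institution_id"].to_numpy()[inst_idx],
            "institution_beds": beds,
            "surgery_date": surgery,
            "enrollment_months_before": rng.integers(12, 49, n),
            "inpatient": ~cov["outpatient"] if "outpatient" in cov else rng.random(n) < 0.31,
            "emergency_or_additional": np.zeros(n, dtype=bool),
        }
    )
    for name, flag in cov.items():
        if name in ("beds_ge_100",):
            continue
        raw[name] = flag

    window = config.test_window_days
    for col in TEST_DATE_COLUMNS:
        p_t = config.test_order_probs.get(col, 0.0)
        ordered = rng.random(n) < p_t
        inside = rng.integers(0, window + 1, n).astype("timedelta64[D]")
        outside = (window + rng.integers(1, 301, n)).astype("timedelta64[D]")
        dates = np.where(outcome, surgery - inside, surgery - outside)
        col_dates = pd.Series(dates, dtype="datetime64[ns]")
        col_dates[~ordered] = pd.NaT
        raw[col] = col_dates
    # a positive latent event must leave at least one order in the window
    any_in_window = np.zeros(n, dtype=bool)
    for col in TEST_DATE_COLUMNS:
        any_in_window |= raw[col].notna().to_numpy()
    force = outcome & ~any_in_window
    if force.any():
        forced = pd.Series(
            surgery - rng.integers(0, window + 1, n).astype("timedelta64[D]"),
            dtype="datetime64[ns]",
        )
        raw.loc[force, "cbc_date"] = forced[force]
    raw["latent_outcome"] = outcome
    return raw


def write_truth(config: SyntheticConfig, path) -> None:
    """Write the generating truth (effects, intercept, variance) as JSON for
    parameter-recovery studies."""
    payload = {
        "true_beta": {k: float(v) for k, v in config.true_beta.items()},
        "true_intercept": config.resolved_intercept(),
        "sigma0_sq": config.sigma0_sq,
        "n_patients": config.n_patients,
        "n_institutions": config.n_institutions,
        "seed": config.seed,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def write_cohort(raw: pd.DataFrame, path) -> None:
    """Write a raw claims table as CSV with ISO-8601 dates."""
    out = raw.copy()
    for col in ["surgery_date", *TEST_DATE_COLUMNS]:
        if col in out.columns:
            out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
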