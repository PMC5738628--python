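"""Two-level Bayesian logistic mixed model fitted by Metropolis-Hastings.

The model for surgery j at institution i, with outcome Y_ij ~ Bernoulli(pi_ij):

    logit(pi_ij) = beta0 + beta1 x_1ij + ... + betap x_pij + c_i
    beta_k  ~ N(0, 1000)          (fixed-effect prior; variance configurable)
    c_i     ~ N(0, sigma0_sq)     (institution random intercept)
    sigma0_sq ~ Gamma(shape 0.001, rate 0.001)

The gamma hyperprior is placed on the variance itself, not on the
precision, and defaults to the conventional diffuse Gamma(0.001, rate
0.001) (scale 1000, prior mean 1); reading 0.001 as the *scale* would give
a prior with mean 1e-6 that forces the random-intercept variance to zero.  The likelihood is the product-Bernoulli form, so rows
sharing an institution and covariate pattern can be aggregated to binomial
sufficient statistics (z successes of n) with an identical log-likelihood
value — aggregation is an algebraic identity here, not an approximation.

Sampling is component-wise random-walk Metropolis: each fixed effect is a
scalar block; the institution intercepts are updated jointly with
independent per-institution proposals (valid because the c_i are
conditionally independent given the fixed effects and sigma0_sq, so the
joint update is a composition of single-site updates); sigma0_sq is updated
on the log scale with the Jacobian correction.  Proposal scales adapt
toward 20-40% acceptance during burn-in only and are frozen afterwards,
preserving detailed balance for the retained draws.

Summaries report posterior-mean coefficients as odds ratios exp(beta_k)
with 95% highest-posterior-density intervals computed on the beta scale and
exponentiated (order-preserving).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .betadiff import Interval
from .cohort import TwoByTwo
from .exceptions import (
    InsufficientSamplesError,
    ParameterError,
    SchemaError,
)

_RECENTER_SWEEPS = 5

__all__ = [
    "GlmmSpec",
    "BinomialData",
    "McmcChains",
    "log_posterior",
    "mh_sample",
    "hpd_interval",
    "summarize",
    "univariate_fit",
    "aggregate_cohort",
]


@dataclass(frozen=True)
class GlmmSpec:
    """Model definition: predictors (in cohort coding) and priors."""

    predictors: tuple = ()
    fixed_prior_mean: float = 0.0
    fixed_prior_variance: float = 1000.0
    hyper_shape: float = 0.001
    hyper_scale: float = 1000.0  # = 1/rate; diffuse Gamma(0.001, rate 0.001)

    def __post_init__(self) -> None:
        if self.fixed_prior_variance <= 0:
            raise ParameterError(
                f"fixed_prior_variance must be positive, got {self.fixed_prior_variance}"
            )
        if self.hyper_shape <= 0 or self.hyper_scale <= 0:
            raise ParameterError("gamma hyperprior parameters must be positive")

    @property
    def coef_names(self) -> list[str]:
        return ["intercept", *self.predictors]


@dataclass(frozen=True)
class BinomialData:
    """Aggregated binomial data: design matrix ``X`` (first column is the
    intercept), successes ``z``, trials ``n`` and, when random intercepts
    are modelled, the 0-based institution index of each row."""

    X: np.ndarray
    z: np.ndarray
    n: np.ndarray
    inst_idx: np.ndarray | None = None
    n_institutions: int = 0

    def __post_init__(self) -> None:
        if self.X.ndim != 2 or len(self.z) != self.X.shape[0] or len(self.n) != self.X.shape[0]:
            raise SchemaError("design matrix and count vectors have mismatched shapes")
        if np.any(self.z < 0) or np.any(self.z > self.n):
            raise SchemaError("need 0 <= z <= n in every aggregated row")

    @property
    def has_random_effects(self) -> bool:
        return self.inst_idx is not None


def aggregate_cohort(cohort: pd.DataFrame, predictors: list[str],
                     random_effects: bool = True) -> BinomialData:
    """Collapse a coded cohort table to binomial sufficient statistics by
    (institution x covariate pattern)."""
    for col in ["outcome", *predictors] + (["institution_id"] if random_effects else []):
        if col not in cohort.columns:
            raise SchemaError(f"cohort table is missing required columns: ['{col}']")
    keys = (["institution_id"] if random_effects else []) + list(predictors)
    if keys:
        g = cohort.groupby(keys, sort=True)["outcome"]
        agg = g.agg(["sum", "size"]).reset_index()
    else:
        agg = pd.DataFrame(
            {"sum": [cohort["outcome"].sum()], "size": [len(cohort)]}
        )
    X = np.column_stack(
        [np.ones(len(agg))] + [agg[p].to_numpy(dtype=float) for p in predictors]
    )
    inst_idx = None
    n_inst = 0
    if random_effects:
        codes, uniques = pd.factorize(agg["institution_id"], sort=True)
        inst_idx = codes.astype(np.intp)
        n_inst = len(uniques)
    return BinomialData(
        X=X,
        z=agg["sum"].to_numpy(dtype=float),
        n=agg["size"].to_numpy(dtype=float),
        inst_idx=inst_idx,
        n_institutions=n_inst,
    )


def _log1pexp(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _loglik_terms(data: BinomialData, beta: np.ndarray, c: np.ndarray | None) -> np.ndarray:
    eta = data.X @ beta
    if c is not None and data.inst_idx is not None:
        eta = eta + c[data.inst_idx]
    return data.z * eta - data.n * _log1pexp(eta)


def log_posterior(
    beta: np.ndarray,
    c: np.ndarray | None,
    sigma0_sq: float,
    data: BinomialData | None,
    spec: GlmmSpec,
) -> float:
    """Joint log-posterior density (up to the marginal-likelihood constant).

    ``data=None`` evaluates the prior alone.  A non-positive sigma0_sq when
    random effects are present returns -inf (a rejected region, not an
    error).
    """
    beta = np.asarray(beta, dtype=float)
    lp = float(
        np.sum(
            stats.norm.logpdf(
                beta, spec.fixed_prior_mean, math.sqrt(spec.fixed_prior_variance)
            )
        )
    )
    if c is not None:
        if sigma0_sq <= 0:
            return -np.inf
        c = np.asarray(c, dtype=float)
        lp += float(np.sum(stats.norm.logpdf(c, 0.0, math.sqrt(sigma0_sq))))
        lp += float(
            stats.gamma.logpdf(sigma0_sq, a=spec.hyper_shape, scale=spec.hyper_scale)
        )
    if data is not None:
        lp += float(np.sum(_loglik_terms(data, beta, c)))
    return lp


@dataclass
class McmcChains:
    """Posterior draws from one chain, post burn-in and thinning."""

    draws: dict  # name -> 1-D array; 'c' -> (n_kept, n_institutions)
    n_iter: int
    burn_in: int
    thin: int
    seed: int | None
    acceptance_rates: dict
    coef_names: list

    @property
    def n_kept(self) -> int:
        return len(next(iter(self.draws.values())))

    def beta_matrix(self) -> np.ndarray:
        return np.column_stack([self.draws[name] for name in self.coef_names])

    def to_frame(self) -> pd.DataFrame:
        cols = {k: v for k, v in self.draws.items() if k != "c"}
        return pd.DataFrame(cols)


def mh_sample(
    data: BinomialData,
    spec: GlmmSpec,
    n_iter: int = 20_000,
    burn_in: int = 500,
    thin: int = 1,
    seed: int | None = None,
    init_beta: np.ndarray | None = None,
    init_sigma0_sq: float = 1.0,
    adapt_interval: int = 50,
) -> McmcChains:
    """Component-block random-walk Metropolis-Hastings sampler.

    Defaults mirror the published run: 20,000 iterations with the first 500
    discarded as burn-in, no thinning.  Proposal scales adapt toward the
    0.2-0.4 acceptance band during burn-in only.  Deterministic given
    ``seed``.
    """
    if not (n_iter > burn_in >= 0):
        raise ParameterError(f"need n_iter > burn_in >= 0, got {n_iter}, {burn_in}")
    if thin < 1:
        raise ParameterError(f"thin must be >= 1, got {thin}")
    p = data.X.shape[1]
    if len(spec.coef_names) != p:
        raise ParameterError(
            f"spec lists {len(spec.coef_names)} coefficients but design has {p} columns"
        )
    rng = np.random.default_rng(seed)
    beta = np.zeros(p) if init_beta is None else np.array(init_beta, dtype=float)
    use_re = data.has_random_effects
    c = np.zeros(data.n_institutions) if use_re else None
    sig = float(init_sigma0_sq)

    with np.errstate(invalid="ignore"):
        lp_lik = _loglik_terms(data, beta, c)
    if not np.all(np.isfinite(lp_lik)):
        raise ParameterError(
            "log-posterior is not finite at initialization; start from the "
            "default state (beta=0, c=0, sigma0_sq=1)"
        )

    prior_sd = math.sqrt(spec.fixed_prior_variance)

    def beta_logprior(b):
        return -0.5 * ((b - spec.fixed_prior_mean) / prior_sd) ** 2

    beta_scales = np.full(p, 0.1)
    c_scale = 0.5
    logsig_scale = 0.5
    acc = {name: 0 for name in spec.coef_names}
    acc["c"] = 0
    acc["sigma0_sq"] = 0
    acc_window = {k: 0 for k in acc}
    n_post = 0

    if use_re:
        # per-institution likelihood bookkeeping for the joint c update
        inst_idx = data.inst_idx
        n_inst = data.n_institutions
        # columns constant within every institution (intercept, bed-size
        # class, teaching status ...) ride a likelihood ridge with the
        # random intercepts: a shift beta_k -> beta_k + delta compensated
        # by c_i -> c_i - delta * x_ik leaves every linear predictor
        # unchanged, so a dedicated recentering move (accepted on the
        # priors alone) is added for each such column to restore mixing.
        inst_level = np.zeros(p, dtype=bool)
        inst_value = np.zeros((n_inst, p))
        for k in range(p):
            col = data.X[:, k]
            lo = np.full(n_inst, np.inf)
            hi = np.full(n_inst, -np.inf)
            np.minimum.at(lo, inst_idx, col)
            np.maximum.at(hi, inst_idx, col)
            if np.all(hi - lo < 1e-12):
                inst_level[k] = True
                inst_value[inst_idx, k] = col
        recenter_scales = np.full(p, 0.1)
        for k in range(p):
            if inst_level[k]:
                acc[f"recenter_{spec.coef_names[k]}"] = 0
                acc_window[f"recenter_{spec.coef_names[k]}"] = 0

    def inst_loglik(c_vec):
        terms = _loglik_terms(data, beta, c_vec)
        return np.bincount(inst_idx, weights=terms, minlength=n_inst)

    cur_loglik = float(np.sum(_loglik_terms(data, beta, c)))

    kept = {name: [] for name in spec.coef_names}
    kept["sigma0_sq"] = []
    kept_c: list = []

    for it in range(n_iter):
        adapting = it < burn_in
        # fixed effects, one scalar block each
        for k in range(p):
            prop = beta.copy()
            prop[k] += rng.normal(0.0, beta_scales[k])
            new_loglik = float(np.sum(_loglik_terms(data, prop, c)))
            logr = (new_loglik - cur_loglik) + beta_logprior(prop[k]) - beta_logprior(beta[k])
            if math.log(rng.random()) < logr:
                beta = prop
                cur_loglik = new_loglik
                acc_window[spec.coef_names[k]] += 1
                if not adapting:
                    acc[spec.coef_names[k]] += 1
        if use_re:
            # joint proposal, independent per-institution accept/reject
            old_il = inst_loglik(c)
            prop_c = c + rng.normal(0.0, c_scale, n_inst)
            new_il = inst_loglik(prop_c)
            logr = (new_il - old_il) - 0.5 * (prop_c**2 - c**2) / sig
            accept = np.log(rng.random(n_inst)) < logr
            c = np.where(accept, prop_c, c)
            acc_window["c"] += float(np.mean(accept))
            if not adapting:
                acc["c"] += float(np.mean(accept))
            cur_loglik = float(np.sum(_loglik_terms(data, beta, c)))
            # sigma0_sq on the log scale with Jacobian
            log_sig_prop = math.log(sig) + rng.normal(0.0, logsig_scale)
            sig_prop = math.exp(log_sig_prop)

            def sig_logpost(s):
                return (
                    float(np.sum(stats.norm.logpdf(c, 0.0, math.sqrt(s))))
                    + float(stats.gamma.logpdf(s, a=spec.hyper_shape, scale=spec.hyper_scale))
                    + math.log(s)  # Jacobian of the log transform
                )

            if math.log(rng.random()) < sig_logpost(sig_prop) - sig_logpost(sig):
                sig = sig_prop
                acc_window["sigma0_sq"] += 1
                if not adapting:
                    acc["sigma0_sq"] += 1
            # recentering moves along the beta/c likelihood ridge; they
            # cost no likelihood evaluation, so several sweeps per
            # iteration buy mixing for free
            for _sweep in range(_RECENTER_SWEEPS):
                for k in range(p):
                    if not inst_level[k]:
                        continue
                    delta = rng.normal(0.0, recenter_scales[k])
                    new_c = c - delta * inst_value[:, k]
                    logr = (
                        beta_logprior(beta[k] + delta)
                        - beta_logprior(beta[k])
                        - 0.5 * (np.sum(new_c**2) - np.sum(c**2)) / sig
                    )
                    if math.log(rng.random()) < logr:
                        beta = beta.copy()
                        beta[k] += delta
                        c = new_c
                        key = f"recenter_{spec.coef_names[k]}"
                        acc_window[key] += 1 / _RECENTER_SWEEPS
                        if not adapting:
                            acc[key] += 1 / _RECENTER_SWEEPS

        if adapting and (it + 1) % adapt_interval == 0:
            for k in range(p):
                rate = acc_window[spec.coef_names[k]] / adapt_interval
                beta_scales[k] *= math.exp(0.5 * (rate - 0.3))
            if use_re:
                c_scale *= math.exp(0.5 * (acc_window["c"] / adapt_interval - 0.3))
                logsig_scale *= math.exp(
                    0.5 * (acc_window["sigma0_sq"] / adapt_interval - 0.3)
                )
                for k in range(p):
                    if inst_level[k]:
                        key = f"recenter_{spec.coef_names[k]}"
                        recenter_scales[k] *= math.exp(
                            0.5 * (acc_window[key] / adapt_interval - 0.3)
                        )
            acc_window = {k: 0 for k in acc_window}

        if it >= burn_in:
            n_post += 1
            if (it - burn_in) % thin == 0:
                for k, name in enumerate(spec.coef_names):
                    kept[name].append(beta[k])
                kept["sigma0_sq"].append(sig if use_re else np.nan)
                if use_re:
                    kept_c.append(c.copy())

    draws = {name: np.asarray(v) for name, v in kept.items()}
    if use_re:
        draws["c"] = np.asarray(kept_c)
    rates = {
        k: (v / n_post if n_post else 0.0) for k, v in acc.items()
    }
    return McmcChains(
        draws=draws,
        n_iter=n_iter,
        burn_in=burn_in,
        thin=thin,
        seed=seed,
        acceptance_rates=rates,
        coef_names=spec.coef_names,
    )


def hpd_interval(samples: np.ndarray, level: float = 0.95) -> Interval:
    """Highest-posterior-density interval by the sliding-window method on
    order statistics (narrowest contiguous window holding ``level`` mass)."""
    if not (0.0 < level < 1.0):
        raise ParameterError(f"level must lie in (0,1), got {level}")
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 100:
        raise InsufficientSamplesError(
            f"need at least 100 samples for an HPD interval, got {n}"
        )
    w = max(1, int(math.ceil(level * n)))
    if w >= n:
        return Interval(float(x[0]), float(x[-1]), level, kind="HPD")
    widths = x[w:] - x[: n - w]
    i = int(np.argmin(widths))
    return Interval(float(x[i]), float(x[i + w]), level, kind="HPD")


def summarize(chains: McmcChains, spec: GlmmSpec, level: float = 0.95) -> pd.DataFrame:
    """Odds-ratio summary: per coefficient, the posterior mean of beta,
    exp(mean) as the odds ratio, and the exponentiated beta-scale HPD."""
    rows = []
    for name in spec.coef_names:
        b = chains.draws[name]
        hpd = hpd_interval(b, level)
        rows.append(
            {
                "predictor": name,
                "posterior_mean_beta": float(np.mean(b)),
                "or": float(np.exp(np.mean(b))),
                "hpd_lower": float(np.exp(hpd.lower)),
                "hpd_upper": float(np.exp(hpd.upper)),
            }
        )
    return pd.DataFrame(rows).set_index("predictor")


def univariate_fit(
    t: TwoByTwo,
    spec: GlmmSpec | None = None,
    n_iter: int = 20_000,
    burn_in: int = 500,
    thin: int = 1,
    seed: int | None = None,
) -> pd.DataFrame:
    """Bayesian logistic fit of logit(pi) = beta0 + beta1 * I(beds >= 100)
    on the 2x2 binomial sufficient statistics, no random effects.

    Returns the odds-ratio summary table; the ``beds_ge_100`` row is the
    institution-size effect.
    """
    if spec is None:
        spec = GlmmSpec(predictors=("beds_ge_100",))
    if any(
        v == 0
        for v in (
            t.z_small,
            t.n_small - t.z_small,
            t.z_large,
            t.n_large - t.z_large,
        )
    ):
        warnings.warn(
            "a margin of the 2x2 table is zero; the fit proceeds, regularized "
            "by the fixed-effect priors",
            stacklevel=2,
        )
    data = BinomialData(
        X=np.array([[1.0, 0.0], [1.0, 1.0]]),
        z=np.array([t.z_small, t.z_large], dtype=float),
        n=np.array([t.n_small, t.n_large], dtype=float),
    )
    chains = mh_sample(data, spec, n_iter=n_iter, burn_in=burn_in, thin=thin, seed=seed)
    return summarize(chains, spec)
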