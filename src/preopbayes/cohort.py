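"""Cohort construction: inclusion/exclusion rules, outcome derivation from
the preoperative test window, and the bed-size 2x2 table.

The analysis cohort is restricted to adults aged 20-64 with at least 12
months of insurance enrollment before the index surgery; inpatient
procedures performed together with additional/emergency procedures are
excluded, as are rows with required fields missing.  The binary outcome is
"any preoperative blood test": at least one of CBC, basic metabolic panel,
coagulation test, or liver function test ordered within a window (default
60 days, closed on both ends, so a same-day order and an order exactly 60
days before surgery both count) before the index procedure.

Rates are carried as exact rationals (``fractions.Fraction``) and rounded
to display precision only at report time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
import json

import numpy as np
import pandas as pd

from .exceptions import EmptyInputError, SchemaError

__all__ = [
    "TEST_DATE_COLUMNS",
    "RAW_REQUIRED_COLUMNS",
    "TwoByTwo",
    "ExclusionLedger",
    "apply_inclusion",
    "derive_outcome",
    "build_cohort",
    "tabulate_beds",
    "overall_rate",
    "group_rates",
    "published_bedsize_table",
]

TEST_DATE_COLUMNS = [
    "cbc_date",
    "metabolic_panel_date",
    "coagulation_date",
    "lft_date",
]

RAW_REQUIRED_COLUMNS = [
    "patient_id",
    "age",
    "sex",
    "institution_id",
    "institution_beds",
    "surgery_date",
    "enrollment_months_before",
    "inpatient",
    "emergency_or_additional",
]

MIN_AGE, MAX_AGE = 20, 64
MIN_ENROLLMENT_MONTHS = 12
DEFAULT_WINDOW_DAYS = 60


@dataclass(frozen=True)
class TwoByTwo:
    """Outcome counts by institution bed-size class.

    ``z_small``/``n_small`` are the test-positive count and total for
    institutions with <100 beds, ``z_large``/``n_large`` for >=100 beds.
    Explicit small/large names are used throughout instead of numeric
    subscripts.
    """

    z_small: int
    n_small: int
    z_large: int
    n_large: int

    def __post_init__(self) -> None:
        for z, n, g in [
            (self.z_small, self.n_small, "small"),
            (self.z_large, self.n_large, "large"),
        ]:
            if not (0 <= z <= n):
                raise SchemaError(f"{g} group needs 0 <= z <= n, got z={z}, n={n}")

    @property
    def n_total(self) -> int:
        return self.n_small + self.n_large

    @property
    def z_total(self) -> int:
        return self.z_small + self.z_large

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "z_small": self.z_small,
                    "n_small": self.n_small,
                    "z_large": self.z_large,
                    "n_large": self.n_large,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "TwoByTwo":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["z_small"], d["n_small"], d["z_large"], d["n_large"])


@dataclass
class ExclusionLedger:
    """Counts of rows dropped per inclusion rule, applied in order.

    Mirrors a study flow diagram: each rule's count is the number of rows
    removed by that rule among rows surviving all earlier rules.
    """

    n_input: int = 0
    missing_required: int = 0
    age_out_of_range: int = 0
    insufficient_enrollment: int = 0
    inpatient_with_additional: int = 0
    n_included: int = 0

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "dropped": {
                "missing_required": self.missing_required,
                "age_out_of_range": self.age_out_of_range,
                "insufficient_enrollment": self.insufficient_enrollment,
                "inpatient_with_additional": self.inpatient_with_additional,
            },
            "n_included": self.n_included,
        }

    def flow_report(self) -> str:
        d = self.as_dict()
        lines = [f"Surgeries assessed: {d['n_input']}"]
        for rule, cnt in d["dropped"].items():
            lines.append(f"  excluded ({rule.replace('_', ' ')}): {cnt}")
        lines.append(f"Surgeries included: {d['n_included']}")
        return "\n".join(lines)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2)


def _check_schema(raw: pd.DataFrame) -> None:
    missing = [c for c in RAW_REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"raw claims table is missing required columns: {missing}")


def apply_inclusion(raw: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionLedger]:
    """Filter a raw claims table to the analysis population.

    Rules, applied in order: required fields present; age within
    [20, 64]; enrollment of at least 12 months before surgery; not an
    inpatient procedure combined with additional/emergency procedures.
    Returns the surviving rows (raw schema preserved) and the exclusion
    ledger.  Idempotent: re-applying to its own output drops nothing.
    """
    _check_schema(raw)
    ledger = ExclusionLedger(n_input=len(raw))
    keep = raw

    ok = keep[RAW_REQUIRED_COLUMNS].notna().all(axis=1)
    ledger.missing_required = int((~ok).sum())
    keep = keep[ok]

    ok = (keep["age"] >= MIN_AGE) & (keep["age"] <= MAX_AGE)
    ledger.age_out_of_range = int((~ok).sum())
    keep = keep[ok]

    ok = keep["enrollment_months_before"] >= MIN_ENROLLMENT_MONTHS
    ledger.insufficient_enrollment = int((~ok).sum())
    keep = keep[ok]

    drop = keep["inpatient"].astype(bool) & keep["emergency_or_additional"].astype(bool)
    ledger.inpatient_with_additional = int(drop.sum())
    keep = keep[~drop]

    ledger.n_included = len(keep)
    return keep.copy(), ledger


def derive_outcome(
    raw: pd.DataFrame, window_days: int = DEFAULT_WINDOW_DAYS
) -> pd.Series:
    """True iff any blood-test order date falls within the preoperative
    window: 0 <= surgery_date - order_date <= window_days.

    Absent dates never trigger the outcome.  The window is closed on both
    ends; widening it can only turn negatives into positives.
    """
    if "surgery_date" not in raw.columns:
        raise SchemaError("raw claims table is missing required columns: ['surgery_date']")
    surgery = pd.to_datetime(raw["surgery_date"])
    out = pd.Series(False, index=raw.index)
    for col in TEST_DATE_COLUMNS:
        if col not in raw.columns:
            continue
        d = pd.to_datetime(raw[col])
        delta = (surgery - d).dt.days
        out |= delta.between(0, window_days).fillna(False)
    return out


def _operations_quartile(cohort: pd.DataFrame) -> pd.Series:
    """Within-cohort quartile (1-4) of each row's institution surgery count,
    nearest-rank on institution-level counts; tied counts share a quartile."""
    counts = cohort.groupby("institution_id").size()
    ranked = counts.rank(method="average", pct=True)
    inst_q = pd.Series(np.searchsorted([0.25, 0.5, 0.75], ranked, side="left") + 1,
                       index=ranked.index)
    return cohort["institution_id"].map(inst_q).astype(int)


def build_cohort(
    raw: pd.DataFrame, window_days: int = DEFAULT_WINDOW_DAYS
) -> tuple[pd.DataFrame, ExclusionLedger]:
    """Full pipeline: inclusion filter, outcome derivation, covariate coding.

    Returns the coded cohort table (one row per included surgery, with
    ``beds_ge_100``, ``n_operations_quartile`` and boolean ``outcome``) and
    the exclusion ledger.
    """
    included, ledger = apply_inclusion(raw)
    cohort = included.copy()
    cohort["outcome"] = derive_outcome(included, window_days)
    cohort["beds_ge_100"] = cohort["institution_beds"] >= 100
    cohort["n_operations_quartile"] = _operations_quartile(cohort)
    return cohort, ledger


def tabulate_beds(cohort: pd.DataFrame) -> TwoByTwo:
    """Partition the cohort into the bed-size 2x2 table of outcome counts."""
    if len(cohort) == 0:
        raise EmptyInputError("cannot tabulate an empty cohort")
    for col in ("beds_ge_100", "outcome"):
        if col not in cohort.columns:
            raise SchemaError(f"cohort table is missing required columns: ['{col}']")
    large = cohort["beds_ge_100"].astype(bool)
    outcome = cohort["outcome"].astype(bool)
    return TwoByTwo(
        z_small=int((outcome & ~large).sum()),
        n_small=int((~large).sum()),
        z_large=int((outcome & large).sum()),
        n_large=int(large.sum()),
    )


def overall_rate(t: TwoByTwo) -> Fraction:
    """Overall outcome proportion as an exact rational."""
    if t.n_total == 0:
        raise EmptyInputError("overall rate undefined for zero total count")
    return Fraction(t.z_total, t.n_total)


def group_rates(t: TwoByTwo) -> tuple[Fraction, Fraction]:
    """(small-bed rate, large-bed rate) as exact rationals."""
    if t.n_small == 0 or t.n_large == 0:
        raise EmptyInputError("group rate undefined for an empty group")
    return Fraction(t.z_small, t.n_small), Fraction(t.z_large, t.n_large)


def published_bedsize_table() -> TwoByTwo:
    """The packaged published 2x2 counts (69,252 low-risk surgeries)."""
    ref = resources.files("preopbayes").joinpath("data/bedsize_counts.json")
    d = json.loads(ref.read_text())
    return TwoByTwo(d["z_small"], d["n_small"], d["z_large"], d["n_large"])
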