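"""CKD prevalence against age-dependent lower reference limits.

A patient is classified as having reduced kidney function when their eGFR
lies strictly below the lower reference limit for their (floored) age.
Prevalence is the fraction of classified patients in a validation cohort,
with a normal-approximation confidence interval

    p ± z · sqrt(p (1 − p) / n),   z = 1.96,

clamped to [0, 1].  Estimates are produced overall and within the
age-adapted strata 30–40, 41–65 and 66–85 years (floored age).

Classification uses the full-precision LRL by default; the rounded
integer display values can be selected for sensitivity analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quantile_reflim import floor_age

logger = logging.getLogger(__name__)

__all__ = [
    "AGE_GROUPS",
    "PrevalenceEstimate",
    "is_below_lrl",
    "prevalence",
    "prevalence_by_age_group",
]

Z_95 = 1.96

#: age-adapted strata on floored age, inclusive bounds
AGE_GROUPS = (("30-40", 30, 40), ("41-65", 41, 65), ("66-85", 66, 85))


@dataclass(frozen=True)
class PrevalenceEstimate:
    """Proportion below the LRL with its normal-approximation 95 % CI."""

    p: float
    ci_low: float
    ci_high: float
    n: int
    n_below: int
    stratum: str = "overall"
    model_id: str = ""
    formula: str = ""
    cohort_id: str = ""

    def as_dict(self) -> dict:
        return {
            "cohort_id": self.cohort_id,
            "formula": self.formula,
            "model_id": self.model_id,
            "stratum": self.stratum,
            "n": self.n,
            "n_below": self.n_below,
            "p": self.p,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        }


def _lrl_lookup(lrl_table: pd.DataFrame, rounded: bool) -> pd.Series:
    col = "lrl_rounded" if rounded else "lrl"
    return lrl_table.set_index("age")[col].astype(float)


def is_below_lrl(egfr, age, lrl_table: pd.DataFrame, rounded: bool = False):
    """Strictly-below-LRL classification at floored age.

    Returns a float array: 1.0 below, 0.0 at or above, NaN for ages outside
    the table (such records are excluded from prevalence with a logged
    count, since the limits are undefined there).
    """
    egfr = np.atleast_1d(np.asarray(egfr, dtype=float))
    fage = np.atleast_1d(floor_age(age)).astype(float)
    lookup = _lrl_lookup(lrl_table, rounded)
    out = np.full(egfr.shape, np.nan)
    in_range = np.isin(fage, lookup.index.to_numpy())
    limits = lookup.reindex(fage[in_range]).to_numpy()
    out[in_range] = (egfr[in_range] < limits).astype(float)
    return out


def _estimate(n: int, n_below: int, **meta) -> PrevalenceEstimate:
    if n == 0:
        return PrevalenceEstimate(p=float("nan"), ci_low=float("nan"),
                                  ci_high=float("nan"), n=0, n_below=0, **meta)
    p = n_below / n
    half = Z_95 * np.sqrt(p * (1.0 - p) / n)
    return PrevalenceEstimate(
        p=p,
        ci_low=max(0.0, p - half),
        ci_high=min(1.0, p + half),
        n=n,
        n_below=n_below,
        **meta,
    )


def prevalence(
    cohort: pd.DataFrame,
    lrl_table: pd.DataFrame,
    rounded: bool = False,
    model_id: str = "",
) -> PrevalenceEstimate:
    """Overall prevalence of eGFR below the age-dependent LRL."""
    if cohort.empty:
        raise ValueError("prevalence is undefined on an empty cohort")
    flags = is_below_lrl(cohort["egfr"].to_numpy(), cohort["age_exact"].to_numpy(),
                         lrl_table, rounded=rounded)
    n_dropped = int(np.isnan(flags).sum())
    if n_dropped:
        logger.info("%d records outside the LRL age range dropped", n_dropped)
    valid = flags[~np.isnan(flags)]
    return _estimate(n=valid.size, n_below=int(valid.sum()), stratum="overall",
                     **_meta(cohort, lrl_table, model_id))


def _meta(cohort: pd.DataFrame, lrl_table: pd.DataFrame, model_id: str) -> dict:
    if not model_id and "model_id" in lrl_table:
        model_id = str(lrl_table["model_id"].iloc[0])
    return {
        "model_id": model_id,
        "formula": str(cohort["formula"].iloc[0]) if "formula" in cohort else "",
        "cohort_id": str(cohort["cohort_id"].iloc[0]) if "cohort_id" in cohort else "",
    }


def prevalence_by_age_group(
    cohort: pd.DataFrame,
    lrl_table: pd.DataFrame,
    groups=AGE_GROUPS,
    rounded: bool = False,
    model_id: str = "",
) -> list[PrevalenceEstimate]:
    """One prevalence estimate per age stratum (floored age, inclusive bounds).

    The strata partition 30–85, so stratum counts sum to the overall count.
    An empty stratum yields an estimate with ``n = 0`` and NaN proportion.
    """
    if cohort.empty:
        raise ValueError("prevalence is undefined on an empty cohort")
    fage = floor_age(cohort["age_exact"].to_numpy())
    flags = is_below_lrl(cohort["egfr"].to_numpy(), cohort["age_exact"].to_numpy(),
                         lrl_table, rounded=rounded)
    meta = _meta(cohort, lrl_table, model_id)
    out = []
    for label, lo, hi in groups:
        mask = (fage >= lo) & (fage <= hi) & ~np.isnan(flags)
        out.append(
            _estimate(n=int(mask.sum()), n_below=int(flags[mask].sum()),
                      stratum=label, **meta)
        )
    return out
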