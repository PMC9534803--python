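"""Build analysis cohorts from raw laboratory submission records.

A *lab record* is one specimen submission: patient identifier, sex, specimen
date, age at specimen, serum creatinine (mg/dl), a four-field urinalysis
panel and the sender type of the submitting institution.  Records live in a
pandas DataFrame with the columns of :data:`LAB_COLUMNS`.

Four cohort kinds are produced:

``model1``
    Reference cohort for the one-time-measurement model: practice senders
    only, inconspicuous (and complete) urinalysis, ages 30–85, first
    submission per patient.
``model2``
    Reference cohort under the chronicity criterion: same eligibility,
    then first/last measurement pairs with 0.25–3 years between them and
    at most ±10 % eGFR change.  The later measurement (and the age at the
    later measurement) is what enters modelling.
``validation1``
    All senders, no urinalysis requirement, first value per patient.
``validation2``
    All senders, stable first/last pairs over a 0.25–1.0 year window.

The pairing-based cohorts depend on the eGFR formula through the percent
change criterion, so one cohort exists per formula.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .egfr_models import FORMULAS

logger = logging.getLogger(__name__)

__all__ = [
    "LAB_COLUMNS",
    "URINALYSIS_COLUMNS",
    "URINALYSIS_LIMITS",
    "SENDER_TYPES",
    "CohortSpec",
    "COHORT_SPECS",
    "urinalysis_pass",
    "first_submission_per_patient",
    "stable_pairs",
    "build_cohort",
]

#: canonical column order of a lab-record table
LAB_COLUMNS = [
    "patient_id",
    "sex",
    "specimen_date",
    "age_at_specimen",
    "scr_mgdl",
    "u_protein_mgdl",
    "u_blood_mgdl",
    "u_leuko_per_ul",
    "u_glucose_mgdl",
    "sender_type",
]

URINALYSIS_COLUMNS = [
    "u_protein_mgdl",
    "u_blood_mgdl",
    "u_leuko_per_ul",
    "u_glucose_mgdl",
]

#: exclusive upper limits for an inconspicuous urinalysis
URINALYSIS_LIMITS = {
    "u_protein_mgdl": 10.0,
    "u_blood_mgdl": 0.015,
    "u_leuko_per_ul": 25.0,
    "u_glucose_mgdl": 20.0,
}

SENDER_TYPES = ("practice", "hospital", "nephrology", "dialysis")

DAYS_PER_YEAR = 365.25


def urinalysis_pass(records: pd.DataFrame) -> pd.Series:
    """Three-valued urinalysis verdict per record.

    ``True`` iff all four strict inequalities hold (proteinuria < 10 mg/dl,
    urine blood < 0.015 mg/dl, leukocytes < 25/µl, glucose < 20 mg/dl);
    ``False`` if any measured field is at or above its limit; ``pd.NA`` when
    any field is missing, which makes the record ineligible for the model
    cohorts rather than failing.
    """
    verdict = pd.Series(True, index=records.index, dtype="boolean")
    for col, limit in URINALYSIS_LIMITS.items():
        vals = records[col]
        verdict &= pd.array(vals < limit, dtype="boolean")
        verdict[vals.isna()] = pd.NA
    return verdict


def _ordered(records: pd.DataFrame) -> pd.DataFrame:
    # deterministic chronological order; ties broken by lower creatinine,
    # then by a stable index so the outcome never depends on input order
    out = records.sort_values(
        ["patient_id", "specimen_date", "scr_mgdl"], kind="mergesort"
    )
    return out


def first_submission_per_patient(records: pd.DataFrame) -> pd.DataFrame:
    """Earliest submission of each patient (ties: lowest creatinine)."""
    if records.empty:
        return records.copy()
    return _ordered(records).groupby("patient_id", sort=False).head(1)


def stable_pairs(
    records: pd.DataFrame,
    formula: str,
    min_dt: float = 0.25,
    max_dt: float = 3.0,
    max_abs_pct: float = 10.0,
) -> pd.DataFrame:
    """First/last measurement pairs with stable kidney function.

    For every patient with at least two submissions the chronologically
    first and last records are paired.  A pair is kept iff the elapsed time
    lies in ``[min_dt, max_dt]`` years and the eGFR percent change
    ``(egfr_last − egfr_first) / egfr_first · 100`` lies within
    ``±max_abs_pct`` (boundaries inclusive).  Returns one row per kept pair
    with first/last fields, ``delta_t_years`` and ``pct_change``.
    """
    if formula not in FORMULAS:
        raise KeyError(f"unknown eGFR formula {formula!r}")
    if records.empty:
        return _empty_pairs()
    ordered = _ordered(records)
    grp = ordered.groupby("patient_id", sort=False)
    first = grp.head(1).set_index("patient_id")
    last = grp.tail(1).set_index("patient_id")
    multi = grp.size() >= 2
    idx = multi[multi].index
    first, last = first.loc[idx], last.loc[idx]
    if first.empty:
        return _empty_pairs()

    fn = FORMULAS[formula]
    egfr_first = fn(first["scr_mgdl"].to_numpy(), first["age_at_specimen"].to_numpy(),
                    first["sex"].to_numpy())
    egfr_last = fn(last["scr_mgdl"].to_numpy(), last["age_at_specimen"].to_numpy(),
                   last["sex"].to_numpy())
    delta_t = (
        last["specimen_date"].to_numpy() - first["specimen_date"].to_numpy()
    ) / np.timedelta64(1, "D") / DAYS_PER_YEAR
    pct = (egfr_last - egfr_first) / egfr_first * 100.0

    pairs = pd.DataFrame(
        {
            "patient_id": first.index,
            "sex": first["sex"].to_numpy(),
            "sender_type_first": first["sender_type"].to_numpy(),
            "sender_type_last": last["sender_type"].to_numpy(),
            "date_first": first["specimen_date"].to_numpy(),
            "date_last": last["specimen_date"].to_numpy(),
            "age_first": first["age_at_specimen"].to_numpy(),
            "age_last": last["age_at_specimen"].to_numpy(),
            "scr_first": first["scr_mgdl"].to_numpy(),
            "scr_last": last["scr_mgdl"].to_numpy(),
            "egfr_first": egfr_first,
            "egfr_last": egfr_last,
            "delta_t_years": delta_t,
            "pct_change": pct,
            "formula": formula,
        }
    )
    keep = (
        (pairs["delta_t_years"] >= min_dt)
        & (pairs["delta_t_years"] <= max_dt)
        & (pairs["pct_change"].abs() <= max_abs_pct)
    )
    return pairs[keep].reset_index(drop=True)


def _empty_pairs() -> pd.DataFrame:
    cols = [
        "patient_id", "sex", "sender_type_first", "sender_type_last",
        "date_first", "date_last", "age_first", "age_last",
        "scr_first", "scr_last", "egfr_first", "egfr_last",
        "delta_t_years", "pct_change", "formula",
    ]
    return pd.DataFrame(columns=cols)


@dataclass(frozen=True)
class CohortSpec:
    """Parameterisation of one analysis cohort."""

    cohort_id: str
    require_urinalysis: bool  # complete and inconspicuous panel
    practice_only: bool
    paired: bool
    min_dt: float = 0.25
    max_dt: float = 3.0
    max_abs_pct: float = 10.0
    age_min: float = 30.0
    age_max: float = 85.0


COHORT_SPECS = {
    "model1": CohortSpec("model1", require_urinalysis=True, practice_only=True,
                         paired=False),
    "model2": CohortSpec("model2", require_urinalysis=True, practice_only=True,
                         paired=True, min_dt=0.25, max_dt=3.0),
    "validation1": CohortSpec("validation1", require_urinalysis=False,
                              practice_only=False, paired=False),
    "validation2": CohortSpec("validation2", require_urinalysis=False,
                              practice_only=False, paired=True,
                              min_dt=0.25, max_dt=1.0),
}


def build_cohort(records: pd.DataFrame, spec: str | CohortSpec, formula: str) -> pd.DataFrame:
    """Assemble one analysis cohort.

    Returns one row per included patient with the columns ``patient_id``,
    ``sex``, ``age`` (floored integer age carried into modelling /
    classification — the age at the later measurement for paired cohorts),
    ``age_exact``, ``scr_mgdl``, ``egfr`` (under ``formula``; the later
    value for paired cohorts), ``cohort_id`` and ``formula``.
    """
    if isinstance(spec, str):
        try:
            spec = COHORT_SPECS[spec]
        except KeyError:
            raise ValueError(
                f"unknown cohort spec {spec!r}; expected one of {sorted(COHORT_SPECS)}"
            ) from None
    if formula not in FORMULAS:
        raise KeyError(f"unknown eGFR formula {formula!r}")

    n_in = len(records)
    eligible = records
    in_age = eligible["age_at_specimen"].between(spec.age_min, spec.age_max)
    eligible = eligible[in_age]
    if spec.practice_only:
        eligible = eligible[eligible["sender_type"] == "practice"]
    if spec.require_urinalysis:
        verdict = urinalysis_pass(eligible)
        eligible = eligible[verdict.fillna(False).to_numpy(dtype=bool)]  # NA = ineligible
    logger.info(
        "cohort %s (%s): %d records in, %d eligible after row filters",
        spec.cohort_id, formula, n_in, len(eligible),
    )

    if spec.paired:
        pairs = stable_pairs(eligible, formula, spec.min_dt, spec.max_dt,
                             spec.max_abs_pct)
        cohort = pd.DataFrame(
            {
                "patient_id": pairs["patient_id"],
                "sex": pairs["sex"],
                "age_exact": pairs["age_last"],
                "scr_mgdl": pairs["scr_last"],
                "egfr": pairs["egfr_last"],
            }
        )
        # pair ages may drift past the upper bound between measurements
        cohort = cohort[cohort["age_exact"].between(spec.age_min, spec.age_max)]
    else:
        firsts = first_submission_per_patient(eligible)
        fn = FORMULAS[formula]
        egfr = (
            fn(firsts["scr_mgdl"].to_numpy(), firsts["age_at_specimen"].to_numpy(),
               firsts["sex"].to_numpy())
            if len(firsts)
            else np.array([])
        )
        cohort = pd.DataFrame(
            {
                "patient_id": firsts["patient_id"].to_numpy(),
                "sex": firsts["sex"].to_numpy(),
                "age_exact": firsts["age_at_specimen"].to_numpy(),
                "scr_mgdl": firsts["scr_mgdl"].to_numpy(),
                "egfr": egfr,
            }
        )
    cohort = cohort.reset_index(drop=True)
    cohort["age"] = np.floor(cohort["age_exact"].to_numpy(dtype=float)).astype(int) \
        if len(cohort) else pd.Series(dtype=int)
    cohort["cohort_id"] = spec.cohort_id
    cohort["formula"] = formula
    if cohort.empty:
        logger.warning("cohort %s (%s) is empty", spec.cohort_id, formula)
    return cohort
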