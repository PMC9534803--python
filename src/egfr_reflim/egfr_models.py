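"""Creatinine-based eGFR equations and age-dependent comparator limits.

Implements the three estimating equations used throughout the pipeline —
the 2009 CKD-EPI creatinine equation, the Full Age Spectrum (FAS) equation
and the European Kidney Function Consortium (EKFC) equation — together with
the Delanaye age-adapted three-stage cut-offs and the continuous FAS-scale
lower-limit comparator derived from them.

Conventions
-----------
* Serum creatinine (Scr) is carried in mg/dl internally.  A µmol/L dialect
  is supported through :func:`scr_umol_to_mgdl` (factor 88.4).
* Sex is one of ``"female"`` / ``"male"``.  FAS and EKFC rescale creatinine
  by the sex-specific healthy-population median Q (0.70 / 0.90 mg/dl).
* The CKD-EPI race coefficient is deliberately omitted: the equations are
  applied to a European laboratory population with no race field.
* eGFR is in ml/min per 1.73 m² body surface area and is kept at full
  floating precision; rounding to integers happens only at reporting
  boundaries.

All scoring functions are vectorised over NumPy arrays / pandas Series and
also accept scalars (returning a Python float).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "InvalidMeasurementError",
    "UnsupportedAgeError",
    "Q_FEMALE",
    "Q_MALE",
    "SCR_UMOL_PER_MGDL",
    "FORMULAS",
    "ckd_epi_2009",
    "fas",
    "ekfc",
    "delanaye_three_stage_threshold",
    "delanaye_continuous_lrl_fas",
    "scr_umol_to_mgdl",
    "scr_mgdl_to_umol",
]

#: sex-specific median serum creatinine of a healthy adult population, mg/dl
Q_FEMALE = 0.70
Q_MALE = 0.90

#: unit conversion factor: 1 mg/dl creatinine = 88.4 µmol/L
SCR_UMOL_PER_MGDL = 88.4


class InvalidMeasurementError(ValueError):
    """A creatinine measurement violates a basic invariant (names the field)."""


class UnsupportedAgeError(ValueError):
    """Age outside the supported adult range of an equation."""


def scr_umol_to_mgdl(scr_umol):
    """Convert serum creatinine from µmol/L to mg/dl."""
    return np.asarray(scr_umol, dtype=float) / SCR_UMOL_PER_MGDL


def scr_mgdl_to_umol(scr_mgdl):
    """Convert serum creatinine from mg/dl to µmol/L."""
    return np.asarray(scr_mgdl, dtype=float) * SCR_UMOL_PER_MGDL


def _validate(scr, age, sex, min_age: float | None = None):
    scr = np.asarray(scr, dtype=float)
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex)
    scalar = scr.ndim == 0 and age.ndim == 0 and sex.ndim == 0
    scr, age, sex = np.atleast_1d(scr), np.atleast_1d(age), np.atleast_1d(sex)
    scr, age, sex = np.broadcast_arrays(scr, age, sex)
    if np.any(~np.isfinite(scr)) or np.any(scr <= 0):
        raise InvalidMeasurementError("scr must be finite and strictly positive")
    if np.any(~np.isfinite(age)) or np.any(age <= 0):
        raise InvalidMeasurementError("age must be finite and strictly positive")
    female = sex == "female"
    if np.any(~female & (sex != "male")):
        bad = sex[~female & (sex != "male")][0]
        raise InvalidMeasurementError(f"sex must be 'female' or 'male', got {bad!r}")
    if min_age is not None and np.any(age < min_age):
        raise UnsupportedAgeError(
            f"age below {min_age} y is outside the adult range of this equation"
        )
    return scr, age, female, scalar


def _ret(values: np.ndarray, scalar: bool):
    return float(values[0]) if scalar else values


def ckd_epi_2009(scr, age, sex):
    """2009 CKD-EPI creatinine equation (race coefficient omitted).

    eGFR = 141 · min(Scr/κ, 1)^α · max(Scr/κ, 1)^(−1.209)
               · 0.993^age · 1.018 [if female]

    with κ = 0.7 (female) / 0.9 (male) and α = −0.329 (female) /
    −0.411 (male).
    """
    scr, age, female, scalar = _validate(scr, age, sex)
    kappa = np.where(female, 0.7, 0.9)
    alpha = np.where(female, -0.329, -0.411)
    ratio = scr / kappa
    egfr = (
        141.0
        * np.minimum(ratio, 1.0) ** alpha
        * np.maximum(ratio, 1.0) ** -1.209
        * 0.993**age
        * np.where(female, 1.018, 1.0)
    )
    return _ret(egfr, scalar)


def _q(female: np.ndarray) -> np.ndarray:
    return np.where(female, Q_FEMALE, Q_MALE)


def _age_factor(age: np.ndarray, rate: float) -> np.ndarray:
    # decline beyond age 40 only; continuous at 40
    return rate ** np.maximum(age - 40.0, 0.0)


def fas(scr, age, sex):
    """Full Age Spectrum equation, adult Q constants.

    eGFR = 107.3 / (Scr/Q), multiplied by 0.988^(age−40) beyond age 40.
    Only the adult regime (age ≥ 20) is supported; the paediatric Q
    schedule is out of scope.
    """
    scr, age, female, scalar = _validate(scr, age, sex, min_age=20.0)
    egfr = 107.3 / (scr / _q(female)) * _age_factor(age, 0.988)
    return _ret(egfr, scalar)


def ekfc(scr, age, sex):
    """European Kidney Function Consortium equation, adult Q constants.

    eGFR = 107.3 · (Scr/Q)^(−0.322) when Scr/Q < 1,
           107.3 · (Scr/Q)^(−1.132) otherwise,
    multiplied by 0.990^(age−40) beyond age 40.  The two power laws meet
    continuously at Scr/Q = 1.  Only age ≥ 25 (constant adult Q) is
    supported.
    """
    scr, age, female, scalar = _validate(scr, age, sex, min_age=25.0)
    ratio = scr / _q(female)
    exponent = np.where(ratio < 1.0, -0.322, -1.132)
    egfr = 107.3 * ratio**exponent * _age_factor(age, 0.990)
    return _ret(egfr, scalar)


#: registry used by the cohort and CLI layers
FORMULAS = {"ckd_epi": ckd_epi_2009, "fas": fas, "ekfc": ekfc}


def delanaye_three_stage_threshold(age):
    """Age-adapted three-stage eGFR cut-off (ml/min/1.73 m²).

    75 below age 40, 60 from 40 to 65, 45 beyond 65.
    """
    age = np.asarray(age, dtype=float)
    scalar = age.ndim == 0
    age = np.atleast_1d(age)
    if np.any((age < 18) | (age > 120)):
        raise UnsupportedAgeError("age must be within [18, 120]")
    out = np.where(age < 40.0, 75.0, np.where(age <= 65.0, 60.0, 45.0))
    return _ret(out, scalar)


def delanaye_continuous_lrl_fas(age):
    """Continuous 2.5th-percentile lower limit on the FAS scale.

    Closed form ``(107.3 / 1.33) · 0.988^max(0, age − 40)``: the FAS
    equation evaluated at the 97.5th-percentile rescaled creatinine
    Scr/Q = 1.33, flat below age 40 (no age-dependent lowering for
    younger adults).  Defined on ages 30–85.
    """
    age = np.asarray(age, dtype=float)
    scalar = age.ndim == 0
    age = np.atleast_1d(age)
    if np.any((age < 30) | (age > 85)):
        raise UnsupportedAgeError("age must be within [30, 85]")
    out = (107.3 / 1.33) * _age_factor(age, 0.988)
    return _ret(out, scalar)
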