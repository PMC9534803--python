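"""Synthetic laboratory cohorts with analytically known eGFR quantiles.

The generator emulates the structure of a large outpatient laboratory
population: adults aged 30–85 submitting serum creatinine (and usually a
same-day urinalysis panel) one or more times over up to a few years, from
practices, hospitals, nephrology practices and dialysis centres.  Its
purpose is to provide ground truth — the exact age-dependent 2.5th
percentile of eGFR — against which the whole estimation pipeline can be
tested.

Statistical model
-----------------
For a patient of age *a*, the log of rescaled creatinine, log(Scr/Q), of a
single non-AKI measurement is a two-component normal mixture:

* with probability ``1 − p_ckd(a)`` (reference component)
      N( μ(a), σ_b(a)² + σ_v² )
* with probability ``p_ckd(a)`` (chronically reduced kidney function)
      N( μ(a) + m_ckd, σ_b(a)² + σ_v² + s_ckd² )

where μ(a) = μ₀ + μ₁·max(0, a − 40) and σ_b(a) = σ₀ + σ₁·max(0, a − 40)
are affine beyond age 40, σ_v is short-term within-patient (biological +
analytical) variation, and the CKD shift m_ckd is drawn once per patient.
The patient-level component (baseline z-score, CKD status and shift) is
constant across a patient's visits; only the visit noise ε ~ N(0, σ_v²)
is redrawn, which is what makes repeated measurements informative.

Acute kidney injury is transient: each visit is independently contaminated
with probability ``p_aki``, multiplying that visit's creatinine by a factor
drawn from a shifted log-normal bounded below by ``min_factor`` without
touching the patient's baseline.

Because Scr/Q is log-normal (mixture) and FAS / EKFC are monotone
decreasing in Scr/Q, the exact 2.5th percentile of non-AKI single-visit
eGFR at each age has a closed form via the 97.5th percentile of the
mixture (:func:`true_lrl`); CKD-EPI does not collapse to Scr/Q, so its
true limit is obtained by a large Monte-Carlo quantile and flagged
approximate.

Urinalysis abnormality probabilities are multiplied by a factor > 1 for
CKD patients, so the inconspicuous-urinalysis filter enriches the
reference component the way a real indirect reference-interval query does.
What the generator does *not* emulate: progressive eGFR decline within a
patient's observation window, seasonal or batch analytical drift, and
inter-laboratory mixing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm, truncnorm

from .cohort_filters import LAB_COLUMNS, URINALYSIS_LIMITS
from .egfr_models import FORMULAS, Q_FEMALE, Q_MALE

__all__ = [
    "AgeModel",
    "CreatinineModel",
    "CkdMixtureModel",
    "AkiModel",
    "VisitModel",
    "UrinalysisModel",
    "SenderModel",
    "SyntheticCohortConfig",
    "make_outpatient_lab_scenario",
    "make_recovery_scenario",
    "generate_cohort",
    "true_lrl",
]

Z_975 = norm.ppf(0.975)  # 1.959964...


class ConfigError(ValueError):
    """A synthetic-cohort configuration field is invalid (names the field)."""


@dataclass(frozen=True)
class AgeModel:
    """Truncated-normal age distribution on [low, high] years.

    A very large ``sd`` makes the distribution effectively uniform.  With
    ``integer=True`` drawn ages are floored to whole years, as laboratory
    information systems often record them.
    """

    mean: float = 57.4
    sd: float = 14.1
    low: float = 30.0
    high: float = 85.0
    integer: bool = False


@dataclass(frozen=True)
class CreatinineModel:
    """Log-normal model of rescaled creatinine Scr/Q.

    ``mu0``/``sigma0`` apply up to age 40; location and between-patient
    scale grow linearly by ``mu_slope``/``sigma_slope`` per year beyond 40.
    ``sigma_visit`` is the within-patient log-sd of a single visit.
    """

    mu0: float = 0.02
    mu_slope: float = 0.004
    sigma0: float = 0.14
    sigma_slope: float = 0.003
    sigma_visit: float = 0.06

    def mu(self, age):
        return self.mu0 + self.mu_slope * np.maximum(np.asarray(age, float) - 40.0, 0.0)

    def sigma_between(self, age):
        return self.sigma0 + self.sigma_slope * np.maximum(
            np.asarray(age, float) - 40.0, 0.0
        )

    def sigma_total(self, age):
        """Log-sd of a single non-AKI measurement at a given age."""
        return np.sqrt(self.sigma_between(age) ** 2 + self.sigma_visit**2)


@dataclass(frozen=True)
class CkdMixtureModel:
    """Age-increasing subpopulation with chronically elevated creatinine."""

    p0: float = 0.03  # prevalence at age 30
    p_slope_per_year: float = 0.004
    log_shift_mean: float = 0.30
    log_shift_sd: float = 0.35

    def p(self, age):
        return np.clip(
            self.p0 + self.p_slope_per_year * (np.asarray(age, float) - 30.0), 0.0, 1.0
        )


@dataclass(frozen=True)
class AkiModel:
    """Transient per-visit creatinine elevation.

    The multiplicative factor is ``min_factor + LogNormal(log_extra_mean,
    log_extra_sd)``, hence always above ``min_factor``.
    """

    p_per_visit: float = 0.08
    min_factor: float = 1.1
    log_extra_mean: float = -0.4
    log_extra_sd: float = 0.5


@dataclass(frozen=True)
class VisitModel:
    """Number of visits (1 + Poisson) and uniform inter-visit gaps, years."""

    extra_visits_lambda: float = 0.9
    gap_min: float = 0.2
    gap_max: float = 1.2


@dataclass(frozen=True)
class UrinalysisModel:
    """Per-record urinalysis panel.

    ``p_missing`` is the chance the submission carried no urine sample at
    all (all four fields null).  Each measured field is abnormal — i.e. at
    or above its exclusion threshold — with its own probability, multiplied
    by ``ckd_odds_factor`` for CKD patients.
    """

    p_missing: float = 0.25
    p_protein: float = 0.04
    p_blood: float = 0.03
    p_leuko: float = 0.05
    p_glucose: float = 0.03
    ckd_odds_factor: float = 4.0


@dataclass(frozen=True)
class SenderModel:
    """Multinomial over sender types (patient-level).

    Separate distributions for reference and CKD patients: nephrology
    practices and dialysis centres predominantly submit specimens of
    patients with known kidney disease.  Sender assignment only
    redistributes patients across senders, so the age-specific eGFR
    marginal of the whole population is unaffected.
    """

    practice: float = 0.84
    hospital: float = 0.12
    nephrology: float = 0.03
    dialysis: float = 0.01
    ckd_practice: float = 0.40
    ckd_hospital: float = 0.18
    ckd_nephrology: float = 0.32
    ckd_dialysis: float = 0.10

    def probs(self, ckd: bool) -> list[float]:
        if ckd:
            return [self.ckd_practice, self.ckd_hospital,
                    self.ckd_nephrology, self.ckd_dialysis]
        return [self.practice, self.hospital, self.nephrology, self.dialysis]


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Full parameterisation of a synthetic laboratory cohort."""

    n_patients: int = 5000
    sex_ratio_female: float = 0.55
    seed: int = 0
    start_date: str = "2020-01-01"
    age: AgeModel = field(default_factory=AgeModel)
    creatinine: CreatinineModel = field(default_factory=CreatinineModel)
    ckd: CkdMixtureModel = field(default_factory=CkdMixtureModel)
    aki: AkiModel = field(default_factory=AkiModel)
    visits: VisitModel = field(default_factory=VisitModel)
    urinalysis: UrinalysisModel = field(default_factory=UrinalysisModel)
    sender: SenderModel = field(default_factory=SenderModel)

    def replace(self, **kwargs) -> "SyntheticCohortConfig":
        return dataclasses.replace(self, **kwargs)

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigError("n_patients must be positive")
        for name, p in [
            ("sex_ratio_female", self.sex_ratio_female),
            ("aki.p_per_visit", self.aki.p_per_visit),
            ("urinalysis.p_missing", self.urinalysis.p_missing),
            ("ckd.p0", self.ckd.p0),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be a probability in [0, 1]")
        if self.creatinine.sigma0 <= 0 or self.creatinine.sigma_visit < 0:
            raise ConfigError("creatinine.sigma0 must be > 0 and sigma_visit >= 0")
        if self.visits.gap_min <= 0 or self.visits.gap_max < self.visits.gap_min:
            raise ConfigError("visits gaps must satisfy 0 < gap_min <= gap_max")
        for ckd in (False, True):
            probs = self.sender.probs(ckd)
            if any(v < 0 for v in probs) or abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigError(
                    "sender probabilities must be non-negative and sum to 1"
                )


def make_outpatient_lab_scenario(**overrides) -> SyntheticCohortConfig:
    """Default scenario shaped like a regional outpatient laboratory.

    Ages are centred at 57.4 (SD 14.1) years; creatinine parameters are
    chosen so mean single-measurement FAS-eGFR lands near 79 ml/min and the
    induced 2.5th-percentile curve declines from the mid-70s at age 30 to
    around 20 ml/min at 85, in line with indirectly estimated reference
    limits for mixed outpatient populations.  AKI contamination and the
    age-increasing CKD mixture are switched on.
    """
    return SyntheticCohortConfig(**overrides)


def make_recovery_scenario(**overrides) -> SyntheticCohortConfig:
    """Estimator-validation scenario with a single-component closed-form truth.

    One visit per patient, no AKI, no CKD mixture, ages uniform over whole
    years 30–85 (flooring is then exact), and a pure log-normal creatinine
    model with gentle post-40 drift: the true 2.5th-percentile curve is
    ``107.3 / exp(μ(a) + 1.96 σ(a)) · 0.988^max(0, a−40)`` and nearly lies
    in the span of the fitting spline, so deviations of the fit measure
    estimation quality rather than model misspecification.
    """
    cfg = SyntheticCohortConfig(
        age=AgeModel(mean=57.5, sd=1e9, low=30.0, high=86.0, integer=True),
        creatinine=CreatinineModel(mu0=0.02, mu_slope=0.002, sigma0=0.14,
                                   sigma_slope=0.0005, sigma_visit=0.06),
        ckd=CkdMixtureModel(p0=0.0, p_slope_per_year=0.0),
        aki=AkiModel(p_per_visit=0.0),
        visits=VisitModel(extra_visits_lambda=0.0),
    )
    return cfg.replace(**overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# generation


def _urinalysis_values(rng, abnormal_p, limit, measured):
    """One urinalysis field: values strictly below the limit when normal,
    at or above it (up to 10x) when abnormal; NaN when not measured."""
    m = abnormal_p.size
    abnormal = rng.random(m) < abnormal_p
    values = np.where(
        abnormal,
        limit * (1.0 + 9.0 * rng.random(m)),
        limit * rng.uniform(0.0, 0.999, m),
    )
    return np.where(measured, values, np.nan)


def generate_cohort(config: SyntheticCohortConfig) -> pd.DataFrame:
    """Generate one lab-record table (one row per specimen submission).

    Deterministic for a fixed config (the seed is part of the config);
    all draws come from a single ``numpy.random.default_rng`` stream in a
    fixed order.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    am, cm, km, akm, vm, um, sm = (
        config.age, config.creatinine, config.ckd, config.aki,
        config.visits, config.urinalysis, config.sender,
    )

    # patient level
    a, b = (am.low - am.mean) / am.sd, (am.high - am.mean) / am.sd
    age0 = truncnorm.rvs(a, b, loc=am.mean, scale=am.sd, size=n, random_state=rng)
    if am.integer:
        age0 = np.floor(age0)
    female = rng.random(n) < config.sex_ratio_female
    z_patient = rng.standard_normal(n)
    is_ckd = rng.random(n) < km.p(age0)
    ckd_shift = np.where(
        is_ckd, rng.normal(km.log_shift_mean, km.log_shift_sd, n), 0.0
    )
    sender_types = np.array(["practice", "hospital", "nephrology", "dialysis"])
    cum_ref = np.cumsum(sm.probs(False))
    cum_ckd = np.cumsum(sm.probs(True))
    u_sender = rng.random(n)
    sender = sender_types[
        np.where(is_ckd,
                 np.searchsorted(cum_ckd, u_sender),
                 np.searchsorted(cum_ref, u_sender)).clip(0, 3)
    ]
    n_visits = 1 + rng.poisson(vm.extra_visits_lambda, n)
    first_offset = rng.uniform(0.0, 1.0, n)  # year within the query window

    # visit level (flattened over patients)
    m = int(n_visits.sum())
    pat = np.repeat(np.arange(n), n_visits)
    gaps = rng.uniform(vm.gap_min, vm.gap_max, m)
    starts = np.concatenate([[0], np.cumsum(n_visits)[:-1]])
    gaps[starts] = 0.0
    elapsed = np.cumsum(gaps) - np.repeat(np.cumsum(gaps)[starts], n_visits)
    t_visit = first_offset[pat] + elapsed
    age_v = age0[pat] + elapsed

    log_ratio = (
        cm.mu(age_v)
        + ckd_shift[pat]
        + z_patient[pat] * cm.sigma_between(age_v)
        + rng.normal(0.0, cm.sigma_visit, m)
    )
    aki_hit = rng.random(m) < akm.p_per_visit
    aki_factor = akm.min_factor + np.exp(
        rng.normal(akm.log_extra_mean, akm.log_extra_sd, m)
    )
    log_ratio = np.where(aki_hit, log_ratio + np.log(aki_factor), log_ratio)
    scr = np.where(female[pat], Q_FEMALE, Q_MALE) * np.exp(log_ratio)

    measured = rng.random(m) >= um.p_missing
    mult = np.where(is_ckd[pat], um.ckd_odds_factor, 1.0)
    panel = {
        col: _urinalysis_values(
            rng, np.minimum(1.0, p_base * mult), URINALYSIS_LIMITS[col], measured
        )
        for col, p_base in zip(
            URINALYSIS_LIMITS, (um.p_protein, um.p_blood, um.p_leuko, um.p_glucose)
        )
    }

    start = pd.Timestamp(config.start_date)
    dates = start + pd.to_timedelta(np.round(t_visit * 365.25).astype(int), unit="D")
    ids = np.char.add("P", np.char.zfill(np.arange(n).astype(str), 6))
    frame = pd.DataFrame(
        {
            "patient_id": ids[pat],
            "sex": np.where(female[pat], "female", "male"),
            "specimen_date": dates,
            "age_at_specimen": age_v,
            "scr_mgdl": scr,
            **panel,
            "sender_type": sender[pat],
        }
    )
    return frame[LAB_COLUMNS]


# ---------------------------------------------------------------------------
# ground truth


def _mixture_logratio_ppf(config: SyntheticCohortConfig, age: float, q: float) -> float:
    """Quantile of single-measurement log(Scr/Q) at a given age (non-AKI)."""
    cm, km = config.creatinine, config.ckd
    mu = float(cm.mu(age))
    s = float(cm.sigma_total(age))
    p_ckd = float(km.p(age))
    s_ckd = np.hypot(s, km.log_shift_sd)

    def cdf(x):
        return (1.0 - p_ckd) * norm.cdf(x, mu, s) + p_ckd * norm.cdf(
            x, mu + km.log_shift_mean, s_ckd
        )

    lo = mu - 10.0 * s_ckd
    hi = mu + km.log_shift_mean + 10.0 * s_ckd
    return brentq(lambda x: cdf(x) - q, lo, hi, xtol=1e-12)


def true_lrl(
    config: SyntheticCohortConfig,
    formula: str,
    age,
    mc_n: int = 400_000,
) -> np.ndarray | float:
    """Exact 2.5th percentile of non-AKI single-visit eGFR at given age(s).

    For FAS and EKFC the limit is the monotone image of the 97.5th
    percentile of the log(Scr/Q) mixture, solved analytically.  CKD-EPI
    does not reduce to Scr/Q, so its limit is approximated by an ``mc_n``-
    draw Monte-Carlo quantile (per sex, mixed at the configured sex ratio)
    and should be treated as approximate.
    """
    ages = np.atleast_1d(np.asarray(age, dtype=float))
    scalar = np.asarray(age).ndim == 0
    if formula in ("fas", "ekfc"):
        out = np.empty_like(ages)
        for j, a in enumerate(ages):
            x975 = _mixture_logratio_ppf(config, a, 0.975)
            ratio = np.exp(x975)
            if formula == "fas":
                val = 107.3 / ratio * 0.988 ** max(a - 40.0, 0.0)
            else:
                expo = -0.322 if ratio < 1.0 else -1.132
                val = 107.3 * ratio**expo * 0.990 ** max(a - 40.0, 0.0)
            out[j] = val
    elif formula == "ckd_epi":
        rng = np.random.default_rng(config.seed + 987_654)
        cm, km = config.creatinine, config.ckd
        out = np.empty_like(ages)
        for j, a in enumerate(ages):
            is_ckd = rng.random(mc_n) < km.p(a)
            shift = np.where(is_ckd, rng.normal(km.log_shift_mean, km.log_shift_sd, mc_n), 0.0)
            log_ratio = rng.normal(float(cm.mu(a)), float(cm.sigma_total(a)), mc_n) + shift
            fem = rng.random(mc_n) < config.sex_ratio_female
            scr = np.where(fem, Q_FEMALE, Q_MALE) * np.exp(log_ratio)
            egfr = FORMULAS["ckd_epi"](scr, np.full(mc_n, a), np.where(fem, "female", "male"))
            out[j] = np.quantile(egfr, 0.025)
    else:
        raise KeyError(f"unknown eGFR formula {formula!r}")
    return float(out[0]) if scalar else out
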