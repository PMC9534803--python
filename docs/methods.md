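# Methods

## Estimand and model

The quantity estimated throughout is the lower reference limit
LRL(age): the 2.5th percentile of eGFR among reference individuals of a
given age, treated as a continuous function of age over 30–85 years.
It is fitted by linear quantile regression of eGFR on a spline basis in
age:

    ŷ(age) = b(age)ᵀ β̂,   β̂ = argmin_β Σᵢ ρ_τ(yᵢ − b(ageᵢ)ᵀβ),

with τ = 0.025 and ρ_τ(u) = u(τ − 1[u<0]) the pinball (check) loss.
Ages are floored to whole years before fitting, so the regression
operates on annual age groups; no other covariates enter (in particular
the two sexes are pooled — the equations' Q-rescaling already absorbs
most of the sex difference in creatinine).

`b(age)` is the full cubic B-spline basis on the knot vector
[30,30,30,30, 40, 85,85,85,85]: five non-negative functions that sum to
one everywhere in [30, 85] and reduce to a single unit entry at either
boundary.  The single interior knot at 40 years reflects the
physiological onset of the age-related eGFR decline.  Because this basis
spans constants, no separate intercept column is added (adding one would
make the design exactly rank-deficient); the span — and therefore the
fitted curve — is identical to the common construction of an intercept
plus an intercept-free spline basis.  Predictions outside [30, 85] are
clamped to the boundary values.

The fit is solved exactly as a linear program (split residuals
u⁺, u⁻ ≥ 0, equality constraints Xβ + u⁺ − u⁻ = y) with the HiGHS
solver.  Quantile-regression optima on discrete data may sit on a flat
LP face; the deterministic solver path fixes the reported coefficient
vector, and tests compare losses, never coefficients.  At an optimum the
fraction of training points strictly below the curve lies within k/n of
τ (k = 5 basis functions), which is asserted as a post-condition.

## eGFR equations

CKD-EPI (2009 creatinine equation, race coefficient omitted — the
intended population is a European laboratory cohort without a race
field), FAS and EKFC, all in mg/dl creatinine with adult Q constants
0.70 (women) / 0.90 (men) mg/dl.  FAS requires age ≥ 20 and EKFC
age ≥ 25; younger ages raise an error rather than silently extrapolating
the paediatric Q schedule.  eGFR values are carried at full precision;
rounding to integers happens only in display tables.  The continuous
comparator limit `(107.3/1.33) · 0.988^max(0, age−40)` is FAS evaluated
at the 97.5th-percentile rescaled creatinine Scr/Q = 1.33 and is flat
below age 40.

## Cohort definitions

One submission record carries patient id, sex, date, age, creatinine and
a four-field urinalysis panel plus the sender type.  An *inconspicuous*
urinalysis requires all four strict inequalities (protein < 10.0 mg/dl,
blood < 0.015 mg/dl, leukocytes < 25/µl, glucose < 20.0 mg/dl); a
missing panel makes a record ineligible for the reference cohorts but
not for validation.  Reference (model) cohorts take practice senders
only; validation cohorts take all senders.

Stable pairs take each patient's chronologically first and last record
and keep the pair when the elapsed time lies in [0.25, 3.0] years
(models) or [0.25, 1.0] years (validation) and the eGFR percent change —
denominator the first measurement — is within ±10 % inclusive.  The age
and eGFR carried into modelling and classification are those of the
*later* measurement.  Ties on identical dates are broken toward the
lower creatinine, making all cohort operations invariant to input
order.  For paired reference cohorts both records must pass urinalysis
(both sit inside the row-filtered eligible set).

## Prevalence

A patient counts as below the limit when eGFR < LRL(⌊age⌋) strictly,
using the full-precision limit by default (classification against the
rounded integer table is available as a sensitivity mode; the unrounded
default avoids a ±0.5 ml/min bias).  The 95 % CI is the plain normal
approximation p ± 1.96·√(p(1−p)/n) clamped to [0, 1]; at p = 0 it
degenerates to a zero-width interval, a documented limitation of that
approximation.  Age strata are 30–40, 41–65 and 66–85 on floored age
(inclusive bounds, a partition — stratum counts always sum to the
overall count).  Records with floored age outside 30–85 are dropped with
a logged count, since the limits are undefined there.

## Synthetic cohorts and ground truth

The generator emulates a regional outpatient laboratory population.  Per
patient: age from a truncated normal (mean 57.4, SD 14.1 years, range
30–85), sex 55 % female, a persistent standard-normal baseline z-score,
and CKD status drawn with probability 0.03 + 0.004·(age−30) (≈ 3 % at 30
rising to ≈ 25 % at 85).  A single non-AKI measurement of log(Scr/Q) is

    N( μ(a) + m·1[CKD],  σ_b(a)² + σ_v² + s²·1[CKD] )

with μ(a) = 0.02 + 0.004·max(0, a−40), σ_b(a) = 0.14 + 0.003·max(0, a−40),
σ_v = 0.06, and a per-patient CKD shift m ~ N(0.30, 0.35²).  The
reference spread matches biological-variation data for creatinine
(between-subject CV ≈ 14 %, within-subject ≈ 6 %); the CKD component is
deliberately broad and overlapping so that the population 2.5th
percentile never falls into a density valley between components — a
requirement for the ground-truth quantile to be statistically
identifiable.  Combined with AKI, single-measurement FAS-eGFR has mean
≈ 79 and SD ≈ 20 ml/min, the shape of a real mixed outpatient cohort.

Visit counts are 1 + Poisson(0.9) with uniform 0.2–1.2-year gaps.  AKI
is transient: each visit independently, with probability 0.08,
multiplies creatinine by 1.1 + LogNormal(−0.4, 0.5) (median ≈ 1.8)
without touching the baseline — so one-time-measurement cohorts carry
spurious low-eGFR dips that the stable-pair filter removes.  Urinalysis
panels are missing as a whole in 25 % of records; each measured field is
abnormal with probability 3–5 %, multiplied by 4 for CKD patients, which
is what makes the inconspicuous-urinalysis filter enrich the reference
component.  Senders are patient-level, with nephrology/dialysis
dominated by CKD patients; since sender assignment only redistributes
patients, the population eGFR marginal per age is unchanged and
`true_lrl` stays exact for unfiltered cohorts.

`true_lrl` inverts the two-component normal-mixture CDF of log(Scr/Q)
at 0.975 (Brent's method, tolerance 1e−12) and maps it through the
monotone FAS/EKFC transforms; for CKD-EPI, which does not reduce to
Scr/Q, it falls back to a 400,000-draw Monte-Carlo quantile and is
flagged approximate.

What the generator does *not* emulate: within-patient progression over
the observation window, analytical drift, seasonal effects, or
between-laboratory mixing.  Passing tests therefore demonstrate that the
pipeline recovers the structure it assumes — not that real populations
satisfy those assumptions.

A second, deliberately simple scenario (`make_recovery_scenario`) is
used to validate the estimator itself: one visit per patient, no AKI, no
CKD mixture, ages uniform over whole years (so the floor-age rule is
exact), and gentle post-40 drift (μ-slope 0.002, σ-slope 0.0005), which
keeps the true curve close to the span of the fitting spline.  Its
closed-form truth is `107.3 / exp(μ(a) + 1.96 σ(a)) · 0.988^max(0,a−40)`.

## Numerical choices and problem sizes

- LP tolerance is HiGHS's default (duality gap ~1e−9); the solver is
  cross-checked in tests against an exhaustive enumeration of
  interpolating solutions on small instances and against an independent
  IRLS quantile-regression routine on larger ones.
- Degenerate designs (all training ages equal) raise an error; constant
  response data are fitted exactly with zero loss.
- Unit dialect: creatinine in mg/dl internally; µmol/L input columns are
  divided by 88.4 on read.
- Test and acceptance problem sizes: estimator-recovery fits use
  n = 5,000 patients, held-out coverage n = 20,000, and each directional
  replicate (five seeded replicates each) uses 20,000 patients — at that
  size the Monte-Carlo noise of the fitted curves (≈ ±1 ml/min interior)
  is safely below the simulated chronicity effect (≈ +3 to +9 ml/min).
- All generation is driven by one `numpy.random.default_rng` stream per
  cohort; identical configs give byte-identical output.

## Known limitations

- At τ = 0.025 the per-age-year sampling noise of an empirical quantile
  is large (≈ 3–4 ml/min at 90 observations per age-year); the spline
  smooths this to ≈ 1 ml/min in the interior but ≈ 2 ml/min near the
  boundary ages, and the C² spline smooths the slope kink at the
  40-year knot with a further ~1–1.5 ml/min local bias when the true
  curve has a hinge there.  Point-wise agreement with ground truth much
  below 2 ml/min at every single age therefore needs reference cohorts
  of roughly 20,000+ rather than 5,000 single measurements.
- The normal-approximation CI is poor for very small prevalences; no
  continuity correction is applied.
- Upper reference limits, sex-stratified curves and confidence bands for
  the quantile curve are out of scope.
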