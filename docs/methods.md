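# Methods

## PDC computation

Coverage and windows are inclusive day sets. A fill on date *d* with *s*
days supplied covers *d … d+s−1*; the one-year observation window is
*index … index+364* (so the maximum denominator is exactly 365 days) and
the predictor window is *index … index+89* (maximum 90 days covered).

**Carry-over.** Fills of one patient are pooled across drug codes within a
therapeutic class and sorted by fill date; each fill's coverage starts at
the later of its fill date and the day after the previous coverage ends.
Stockpiling is uncapped: no limit is placed on how far accumulated supply
can push coverage forward. This is equivalent to a day-by-day "pill
stock" simulation in which each fill adds to a stock and every day with
positive stock consumes one unit — the equivalence is exploited in the
test suite, where the stock simulation serves as an independent oracle for
the interval arithmetic.

**Pre-index supply.** Only fills dated within the 90 days before the index
event contribute; carry-over coverage is built among them (independently
of post-index fills) and the covered days falling on or after the index
date are credited. A consequence of this decomposition is that a fill
older than 90 days cannot chain supply into the window even via later
pre-index fills.

**Hospital credit.** Admission through discharge, inclusive, clipped to
the observation window, on the assumption that hospitals supply inpatient
medication.

**Numerator semantics.** The numerator is the size of the *union* of
pre-supply, post-index and hospital day sets, capped at the denominator.
A plain sum of the three terms can exceed the follow-up time when hospital
stays overlap supply; the union guarantees PDC ≤ 1, which the beta-mean
interpretation of the outcome requires. Overlap is logged at debug level.

**Denominator.** Follow-up days from the index date to the end of
observation (the earliest of index+364, death, administrative end of
study), capped at 365. Patients dying before day 100 are excluded
upstream; deaths between day 100 and day 365 shorten the denominator.

## Cohort rules

One event per patient (the earliest; ties broken by input order). Fixed
exclusion order so ledgers are reproducible: age < 18, pregnancy (a
per-patient flag spanning follow-up; no temporal pregnancy model), death
within 100 days of index, insurer switch within 365 days; for the
antiplatelet cohort additionally oral-anticoagulant use and bleeding
events. "Within 100 days" is read strictly — a death on day 100 survives
(and truncates follow-up instead); the threshold is a parameter. New vs
prevalent user status uses a 365-day pre-index look-back, the conventional
one-year washout, since no shorter window is canonical for this design.

## Prediction models

Single-predictor logit-linear mean equations of a beta regression,
applied through the inverse logit; coefficients are taken as published
(statin −1.65 + 0.04·x, antiplatelet −1.52 + 0.04·x; x = days covered in
the first 90). No refitting is done here: model development belongs to a
separate estimation exercise, and this package's concern is application
and validation. Predictions are strictly inside (0, 1); clipping can only
occur after mean-shift recalibration, which operates on the probability
scale so that (absent clipping) the mean of the predictions moves by
exactly the supplied delta.

The predictor is bounded to [0, 90] days; values outside raise by default
(configurable to warn) because the model was developed on that range.

## Validation metrics

* CITL = mean(observed) − mean(predicted).
* Calibration model fitted by ordinary least squares; the 95% CI for the
  slope uses the normal-theory standard error with a t quantile at n−2
  degrees of freedom (bootstrap was considered and rejected as the
  default: the normal-theory interval is symmetric, cheap and standard
  for this fit). When the fitted slope is exactly 1 the intercept equals
  CITL.
* R²_val is 1 − SSE/SST against the raw predictions without refitting —
  the external-validation convention for "proportion of variance
  explained" — and may be negative for a badly miscalibrated model. The
  squared Pearson correlation and the calibration-model R² are reported
  as secondary fields because the literature is inconsistent about which
  is meant.
* RMSE, MAE, the MAE of a constant predictor at the observed mean, and
  the relative MAE reduction 1 − MAE/baseline-MAE (undefined, reported as
  missing, when the observed outcome is constant).
* Absolute-error quantiles use linear interpolation between order
  statistics; some convention had to be fixed for reproducibility and
  this is numpy's default.
* The calibration curve uses equal-count (decile by default) bins by
  predicted value; bin counts always sum to n.

## Sample-size criteria

Criteria (i)–(iii) are closed-form; the integer minimum is the ceiling of
the raw value, and the overall minimum is the maximum over all four
criteria. Criterion (iv) — precision of the residual spread of the
calibration model — is an exact chi-square search for the smallest n such
that `sqrt(m / chi2.ppf(0.025, m)) ≤ 1 + moe` with residual degrees of
freedom m = n − p − 1. The margin of error is defined on the
standard-deviation scale: that reading yields n = 235 at a 10% margin
with one calibration predictor, consistent with the worked number this
criterion is known by, whereas a variance-scale margin would roughly
double the implied precision demand and give a much larger n.

The CITL criterion's precision target is interpreted as SE = 0.0255 (not
SE² = 0.0255): only the SE reading reproduces the criterion's worked
value of 30.75 → 31 with var(Y) = 0.04 and R² = 0.5. Evaluating the slope
criterion's formula as printed (λ = 1, R² = 0.5, SE = 0.051) gives
385.47 → 386; a sometimes-quoted 393.15 back-solves to SE ≈ 0.0505 and is
not used as an oracle anywhere in this package.

## Synthetic data generator

Two levels, both fully deterministic given the seed.

**Direct outcome pairs** (`generate_outcome_pairs`) draw the predictor
from a three-part mixture — point mass at 0 (weight 0.30), uniform spread
over 1–84 (0.45), near-ceiling block on 85–90 (0.25) — chosen so the
default median (≈30) and IQR (≈0–86) resemble a monthly-refill claims
cohort; only the median/IQR are constrained by observation, so the shape
in between is a modelling choice. Outcomes are beta with mean
inverse-logit(β0 + β1·x) and precision φ (shapes μφ and (1−μ)φ). The beta
has open support, but real cohorts contain full never-takers with PDC
exactly 0: patients with x = 0 therefore receive outcome 0 with
probability 0.5 (configurable), and the continuous component's mean is
rescaled to μ/(1−p₀) so the conditional mean at x = 0 still follows the
model. The compensation keeps the generator a faithful inverse of the
model being validated, which is what makes the metric-recovery tests
(CITL → 0, slope → 1) meaningful.

φ defaults to 3.0, giving outcome dispersion around the mean of the same
order as real claims cohorts (prediction RMSE ≈ 0.2); no published value
of the outcome dispersion exists to match exactly.

**Fill histories** (`generate_fill_histories`) simulate, per patient: an
index date uniform over a ~5.3-year enrolment span from the 2016-01-01
epoch (arbitrary but fixed, for human-readable dates); a refill cycle of
30/60/90 days with probabilities 0.942/0.031/0.027 (monthly dispensing
dominates); an adherence propensity Beta(0.55, 0.45) — U-shaped, putting
mass near both never-refilling and always-refilling; an initiating fill on
the index date realized with probability 0.85 (non-initiators create the
observed mass at zero days covered); then refills scheduled every cycle,
each realized with the patient's propensity and delayed by a geometric lag
(mean 1.5 days — a simple memoryless gap process, since nothing stronger
is known about fill delays), until discontinuation (exponential with
per-day hazard 0.001), death, or day 364. Prevalent users (35.3% for the
statin class) get a pre-index renewal process starting up to a year back,
some of whose fills land inside the 90-day look-back. Hospital stays are
Poisson (0.30 per patient-year) with geometric lengths (mean 6 days).
Exclusion-triggering attributes (under-18, pregnancy, death before day
100, insurer switch, oral-anticoagulant use, bleeding) are sampled at
rates matching the per-rule removal fractions reported for stroke/TIA
claims cohorts; an additional 2.1% die between day 100 and 365, exercising
denominator truncation.

The generator also emits, per patient, the ground-truth set of
supply-covered days in the 1-year window, computed by the day-by-day stock
simulation — deliberately *not* the interval arithmetic of the PDC engine,
so the two can check each other.

**What the simulator does not emulate.** Refill behaviour is a stationary
renewal process tied to a single per-patient propensity, so the
correlation between 90-day and 1-year adherence is structural rather than
behavioural; real cohorts show habit formation, seasonal gaps, dose
changes and primary-nonadherence patterns the simulator lacks. Covariates
beyond what the pipeline consumes (socioeconomic score, diagnoses, dosing)
are not generated. Passing tests therefore demonstrate correctness of the
computational chain and recovery of validation metrics under a known
data-generating process — not that the published models are well
calibrated for any real population.

## Problem sizes

Metric-recovery experiments use 10,000 direct outcome pairs; slope-CI
coverage uses 200 replicates of 2,000 pairs; oracle equivalence uses
1,000 simulated fill histories; the end-to-end smoke test uses 2,000
patients. These sizes keep Monte-Carlo error well below the 3-standard-
error test tolerances while the whole suite runs in seconds.

## Known limitations

* The PDC engine is day-resolution only; dosing frequency is ignored
  (days supplied is authoritative).
* The look-back decomposition cannot credit supply chains that begin
  before the 90-day look-back window (documented above); whether the
  original procedure would is unknowable from its description.
* Whether the 90-day predictor should include hospital credit is
  ambiguous in the source description; it is included here for symmetry
  with the 1-year numerator.
* The "erroneous data" exclusion seen in registry flow counts has no
  operational definition and is not implemented.
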