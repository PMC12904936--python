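# Methods

## The measurement problem

Sudden sensorineural hearing loss (SSNHL) is diagnosed from a pure-tone
audiogram: at least 30 dB of hearing loss over three or more consecutive test
frequencies, arising within 72 hours.  Recovery, however, is conventionally
reported as the change in a *fixed* four-frequency pure-tone average
(PTA4: 500, 1000, 2000, 4000 Hz).  When the lesion lies partly or wholly
outside that band — a low-frequency dip at 250–1000 Hz, a high-frequency
lesion at 3000–8000 Hz — PTA4 dilutes the recovery signal with frequencies
that were never affected.  The individualized pure-tone average (iPTA)
instead averages exactly the patient's consecutive affected frequencies,
determined on the diagnostic audiogram and reused verbatim at follow-up.

## Scoring model

All hearing levels are in dB HL on the grid 125, 250, 500, 1000, 1500, 2000,
3000, 4000, 6000, 8000 Hz, recorded in 5 dB steps in [-10, 120] (no-response
thresholds are clipped at 120).  Thresholds at 500–6000 Hz (omitting
1500/3000) are assumed present on every audiogram; the others are optional.

* **Loss profile.**  By default, loss at a frequency is the *interaural*
  difference: affected-ear threshold minus contralateral-ear threshold.  The
  contralateral ear serves as the patient's premorbid baseline, consistent
  with recovery being judged against the contralateral ear.  An absolute
  mode (loss relative to 0 dB HL) is available via
  `loss_reference="absolute"` for sensitivity use; the interaural
  interpretation is the package default.
* **Run detection.**  An affected run is a maximal block of consecutive
  frequencies with loss ≥ 30 dB, length ≥ 3.  Consecutiveness is evaluated
  over the *measured* frequencies in grid order: an untested frequency
  neither counts as affected nor splits a run, since routinely skipped
  frequencies (125, 1500, 3000, 8000 Hz) would otherwise fragment lesions
  artificially.  A strict-grid mode (unmeasured frequencies break runs) is
  available.
* **iPTA.**  The unrounded arithmetic mean over the union of all qualifying
  runs' frequencies (not only the longest run).  An empty union means the
  SSNHL criterion is not met and is an error, not a value.
* **Degree of loss.**  WHO classes from the affected ear's PTA4:
  no/mild ≤ 40 < moderate ≤ 60 < severe ≤ 80 < profound.  PTA4 from 5 dB
  steps is a multiple of 1.25, so "> 80" and "≥ 81" define the same class.
* **Patterns.**  Low-frequency loss: ≥ 30 dB at 125, 250 and 500 Hz
  (indeterminate if 125/250 Hz untested).  High-frequency loss: a qualifying
  run lying entirely within 3000–8000 Hz.  Frequency-range-specific loss:
  exactly 3 or 4 affected frequencies forming a single run, with loss
  < 30 dB everywhere else measured.
* **Recovery taxonomy.**  Recovery is initial minus follow-up average
  (positive = improvement).  *Full*: follow-up average within 10 dB of the
  contralateral ear over the same frequencies.  *Partial*: not full, but
  improvement > 10 dB.  *None*: improvement ≤ 10 dB (worsening included).
  The three categories partition every case.  Under PTA4 the full criterion
  can already hold at diagnosis (lesion outside the PTA4 band); such cases
  are flagged rather than dropped.
* **Conductive screen.**  A patient is primarily conductive (excluded) when
  the air-bone gap in PTA4 exceeds 10 dB — a common clinical convention; no
  gap threshold is standard in this setting.  Without bone-conduction data
  the check is skipped with a warning, matching retrospective chart review.

## Cohort filters

The inclusion pipeline applies, in order: (1) the SSNHL criterion (run
detection on the diagnostic loss profile, onset within 72 h); (2)
undeterminable onset or more than 30 days from onset to assessment; (3)
primarily conductive loss; (4) a pre-known cause of hearing loss; (5)
treatment initiated more than 3 days before the diagnostic audiogram; (6)
missing diagnostic audiogram or loss to audiometric follow-up; (7) age
under 18.  Each record is excluded by the first rule it violates, so the
ledger counts are order-dependent but conserve totals exactly; the final
included set is order-invariant when violations are disjoint.  Rows that
fail CSV parsing are ledgered as rejections, never silently dropped.

## Statistics

* **Bland-Altman.**  Differences are PTA4 recovery minus iPTA recovery, with
  iPTA as the designated reference method.  Mean difference, SD (n−1), and
  limits of agreement mean ± 1.96·SD.  Proportional bias is estimated by OLS
  of the difference on the *reference value* (the variant appropriate when
  one method is treated as reference), not on the pair mean; the
  conventional difference-vs-mean regression is available via `mode="mean"`.
* **Subgroup comparison.**  Unpaired t-test between iPTA and PTA4 recovery
  within a subgroup.  Welch's unequal-variance flavor is the default (the
  two measures have visibly different spreads); Student's pooled test is an
  option.
* **Per-frequency ANOVA.**  One-way ANOVA of per-frequency recovery, each
  frequency group containing only patients for whom that frequency was
  affected, with Tukey HSD as the post-hoc procedure (the standard follow-up
  where none is otherwise specified).
* **Prognostic models.**  Multivariable OLS of absolute recovery in dB, and
  maximum-likelihood logistic models of full-vs-incomplete recovery (whole
  cohort) and partial-vs-none (fully recovered excluded).  The covariate set
  mirrors the forest plot: age group (reference: middle-aged 40–59), sex,
  degree of loss (reference: no/mild), range-specific flag, dizziness,
  tinnitus, hypertension, diabetes, any corticosteroid treatment (reference:
  none), and disease duration until assessment in days (time to treatment
  start, or to the diagnostic audiogram if untreated).  The logistic models
  default to the same covariates, configurable.  Complete-case analysis;
  Wald 95% CIs; two-sided α = 0.05.  Covariates without variation in a
  fitting subset are dropped and reported; rank-deficient designs are an
  error naming the collinear terms; (quasi-)separation in logistic fits is
  flagged on the result.  Model fitting delegates to statsmodels; this
  package owns the specification of outcomes, subsets and reference levels.
* **Duration subgroups.**  Per treatment arm: a crude simple regression of
  iPTA recovery on duration, and an adjusted model adding age group, degree,
  hypertension, diabetes, tinnitus and dizziness (the covariates unevenly
  distributed between arms).
* **Sensitivity analyses.**  The primary linear model re-fit excluding, in
  turn: patients treated before the diagnostic audiogram, patients with
  non-standard treatment, and patients with a later-identified etiology.

## Synthetic cohort generator

No patient-level data are available, so validation runs on synthetic
cohorts.  The generator is a deliberate caricature that reproduces the
*published* marginals and effect structure, not a biophysical model.

**Covariates.**  Independent draws at the published prevalences (dizziness
0.23, tinnitus 0.50, hypertension 0.36, diabetes 0.13, female 0.46, treated
0.82); age truncated normal 57 ± 17 on [19, 91]; disease duration lognormal
per arm, moment-matched to mean (SD) 5 (6) days treated and 10 (8) days
untreated — day counts are non-negative with SD ≈ mean, so a right-skewed
law is the natural choice — rounded to whole days and capped at the 30-day
inclusion limit.  Treatment mix, pre-audiogram treatment (18% of treated,
1–3 days), and later-identified etiologies (7%) match the cohort
description.

**Audiograms.**  The contralateral ear is a presbycusis caricature: 5 dB
flat plus an age-dependent high-frequency slope (0.45 dB per year above 18,
weighted toward high frequencies), 5 dB quantized.  Optional frequencies are
measured with calibrated probabilities (125: 0.50, 250: 0.85, 1500: 0.35,
3000: 0.50, 8000: 0.90).  The lesion is a run of consecutive measured
frequencies: with probability 0.20 a range-specific run of length 3–4,
otherwise length 5–8; the run-start distribution is a calibrated shape
parameter concentrated on 500–1000 Hz.  Lesion magnitude is drawn per
patient from a severity class (mix 15/20/32/33%) mapped to uniform dB
ranges, at least 30 dB at every run frequency; dizzy patients draw from a
profound-tilted mix (configurable, default on), reproducing the
dizziness-severity association that makes the adjusted/unadjusted contrast
meaningful.

**Recovery.**  True patient-level recovery is a linear predictor plus
Gaussian noise (SD 15 dB): intercept 42.7 dB, dizziness −14.4 dB, tinnitus
−4.9 dB, and arm-specific duration slopes −0.75 (treated) and −0.93
(untreated) dB per day.  The published single multivariable duration
coefficient (−0.84) and the two crude arm slopes cannot all be planted at
once; planting the arm slopes makes the single-slope model recover their
within-arm variance-weighted average (≈ −0.80), which is what the
replicated experiment checks against the published value within its
tolerance.  Within a run, recovery is spread with a frequency gradient
(2.5 dB per grid step, low frequencies recovering more, plus an extra 8 dB
shortfall at 6000/8000 Hz) that is *centred within each run*, so the
run-average recovery equals the linear predictor exactly and planted
coefficients stay unbiased.  The follow-up audiogram applies the per-
frequency recovery to the lesion, floored so the affected ear never
measures more than 20 dB better than the contralateral reference
(a recovered ear can out-hear an age-affected contralateral ear by a
little, and a shallower floor measurably attenuates the planted duration
slope through censoring of strong recoverers), quantized to 5 dB, with 3 dB
follow-up noise on affected and ±5 dB-scale test-retest noise on unaffected
frequencies.  The hidden truth (linear predictor, lesion class, run) is
returned beside the records for tests; no analysis stage reads it.

**Calibration.**  Free shape parameters (run positions and lengths,
measurement rates, recovery intercept, gradient, high-frequency shortfall,
floor) were calibrated with a coordinate grid search
(`calibrate_shape_parameters`) at n = 20,000 against the published
summaries — full recovery 23% (iPTA) and 30% (PTA4), Bland-Altman mean
difference −2.4 dB, range-specific recovery gap 8.7 dB — and the calibrated
values are checked in as the defaults.  `analysis/06_calibration_check.py`
re-verifies them and re-runs a small search around the defaults.

**What the generator does not emulate.**  Only the published marginals are
matched; the joint covariate distribution (beyond the dizziness-severity
tilt and the arm-specific durations) is independence.  Two known deviations
from the source cohort's descriptive table, accepted deliberately: (a) the
partial/no-recovery split is roughly 60/17% here versus the published
38/39% — under a single additive-noise recovery process the published
full-recovery proportions, effect sizes and the 8.7 dB range-specific gap
jointly force a higher mean recovery than the published partial/none split
implies, and the agreement/outcome targets were prioritized; (b) the
measured-PTA4 severity mix skews milder than the drawn lesion-severity mix
because lesions partially overlapping the PTA4 band read as milder.
Passing tests therefore demonstrate correctness of the scoring and
estimation machinery under realistic-but-idealized audiograms, not fidelity
to any real population's joint distribution.

## Numerical and design notes

* Averages are kept as unrounded floats; reports display 0.1 dB.
* All randomness flows from one integer seed through
  `numpy.random.default_rng`; regenerating with the same config and seed is
  bit-identical, and the pipeline logs the seed in every report.
* Replication sizes: 200 cohorts of n = 253 for the parameter-recovery
  experiment (matching the study size), one n = 20,000 cohort for the
  calibration summaries — large enough that the binomial SE of a 23%
  proportion is ~0.3 percentage points.
* With ~23% full recovery at n = 253, logistic fits frequently show
  quasi-separation in the sparse dizzy-and-fully-recovered cell; such fits
  are flagged, and the per-day odds ratio (the quantity under study) remains
  stable (median across replicates ≈ 0.92).
* Follow-up audiograms re-use the diagnostic measurement mask, and the last
  available follow-up is the scoring target when several exist.
* Missing 125/250 Hz makes the low-frequency flag indeterminate (`None`)
  rather than false.

## Known limitations

* The interaural reading of the 30 dB criterion is a design choice; with a
  bilaterally impaired contralateral ear both it and the recovery criterion
  inherit that baseline's imperfection.  No correction is attempted.
* The generator's contralateral template and lesion geometry are
  caricatures; per-frequency recovery magnitudes beyond the planted gradient
  carry no clinical claim.
* The filter order follows the methods prose; per-step exclusion counts are
  order-dependent (conservation and the final set are not).
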