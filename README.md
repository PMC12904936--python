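# ssnhl-ipta

Individualized hearing-recovery measurement and prognostic analysis for
sudden sensorineural hearing loss (SSNHL).

SSNHL is diagnosed as ≥ 30 dB hearing loss over ≥ 3 consecutive audiometric
frequencies within 72 h, yet recovery is conventionally reported as the
change in a fixed four-frequency pure-tone average
(PTA4 = mean of thresholds at 500, 1000, 2000, 4000 Hz).  When the lesion
lies partly outside that band, PTA4 dilutes the signal with unaffected
frequencies.  This package implements the *individual* pure-tone average,

    iPTA = mean of the affected ear's thresholds over exactly the patient's
           consecutive affected frequencies (loss ≥ 30 dB vs the
           contralateral ear), fixed on the diagnostic audiogram,

together with everything needed to study it: the recovery taxonomy (full
recovery = follow-up average within 10 dB of the contralateral ear over the
same frequencies; partial = improvement > 10 dB; none otherwise), the
cohort inclusion/exclusion pipeline with an auditable flowchart ledger,
Bland-Altman method agreement between PTA4 and iPTA recovery, multivariable
linear/logistic prognostic models, per-arm duration regressions and
sensitivity analyses — and a seeded synthetic cohort generator calibrated to
the published cohort structure, since no patient-level data are available.
See `docs/methods.md` for the full model description.

Audience: hearing researchers and biostatisticians who want to score SSNHL
recovery with a frequency-specific measure, or to stress-test recovery
definitions on simulated cohorts.

## Worked example

```python
from ssnhl_ipta import EarThresholds, score_recovery

diagnostic = EarThresholds({250: 60, 500: 65, 1000: 70, 2000: 25,
                            4000: 25, 6000: 30}, side="right")
followup   = EarThresholds({250: 15, 500: 20, 1000: 25, 2000: 25,
                            4000: 25, 6000: 30}, side="right")
contra     = EarThresholds({250: 15, 500: 15, 1000: 20, 2000: 20,
                            4000: 25, 6000: 30}, side="left")

res = score_recovery(diagnostic, followup, contra, measure="ipta")
print(res.frequencies, res.initial_value, res.recovery_db, res.category.value)
# (250, 500, 1000) 65.0 45.0 full

res4 = score_recovery(diagnostic, followup, contra, measure="pta4")
print(round(res4.recovery_db, 1), res4.category.value)
# 22.5 full
```

The lesion touches 250–1000 Hz only, and the ear returns to within 10 dB of
the contralateral ear at those frequencies: iPTA registers the full 45 dB of
recovery where PTA4 sees 22.5 dB — the dilution the individualized measure
removes.

The analysis itself is a sequence of numbered drivers over a simulated
study-sized cohort (n = 253, seed logged in every output):

```bash
python analysis/01_simulate_cohort.py     # cohort.csv + Table-1-style summary
python analysis/02_filter_and_score.py    # filter ledger + per-patient recovery
python analysis/03_method_agreement.py    # Bland-Altman, subgroup gap, ANOVA
python analysis/04_prognostic_models.py   # forest-plot TSV of all models
python analysis/05_parameter_recovery.py  # 200-replicate bias table
python analysis/06_calibration_check.py   # generator-calibration verification
```

Sample output (seed 1):

```
Bland-Altman (PTA4 - iPTA): mean -2.80 dB, LoA (-18.2, 12.6), slope -0.196
range-specific subgroup (n=54): iPTA-PTA4 recovery gap 9.91 dB (Welch p = 0.0008)
linear iPTA dizziness: B = -14.28 dB (-18.71, -9.85), p = 0.0000
logistic full-recovery per day: OR = 0.892 (0.797, 0.998)
```

On a single synthetic cohort the fitted dizziness coefficient (−14.3 dB) and
per-day odds ratio (0.89) scatter around the planted values (−14.4 dB,
≈ 0.92); the 200-replicate experiment in `05_parameter_recovery.py` shows
they are recovered without systematic bias.  Everything is also available as
a CLI (`ssnhl-ipta simulate|filters|score|agreement|prognosis|
recover-params|calibrate|pipeline`) and as library calls
(`ssnhl_ipta.pipeline.run_pipeline`).

## Layout

```
src/ssnhl_ipta/      audiometry (iPTA, runs, taxonomy) · filters · agreement
                     prognosis · simulate (generator + calibration) ·
                     cohort_io (CSV schema) · pipeline · experiments · cli
analysis/            numbered narrative drivers (write to results/)
tests/               pytest suite incl. oracle and invariant checks
docs/methods.md      model description, calibration, limitations
```
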