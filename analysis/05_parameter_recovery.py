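"""Parameter-recovery experiment: do the models recover the planted effects?

Generates 200 independent cohorts of n = 253 from the calibrated default
configuration and fits the full prognostic battery on each.  The averaged
estimates should sit close to the planted effect sizes (dizziness -14.4 dB,
tinnitus -4.9 dB, crude duration slopes -0.75 / -0.93 dB per day); the
single-slope multivariable duration coefficient lands between the two arm
slopes (their within-arm variance-weighted average, ~-0.8 dB/day), and the
full-recovery odds ratio per day of delay sits near 0.92.  Writes the
per-replicate estimates and the bias table under results/.
"""

import warnings

warnings.filterwarnings("ignore")

from pathlib import Path

from ssnhl_ipta.experiments import parameter_recovery_experiment, recovery_summary

OUT = Path(__file__).resolve().parent.parent / "results"
REPS = 200
N = 253
BASE_SEED = 0


def main():
    OUT.mkdir(exist_ok=True)
    est = parameter_recovery_experiment(reps=REPS, n=N, base_seed=BASE_SEED)
    est.to_csv(OUT / "parameter_recovery_replicates.csv", index=False)
    summary = recovery_summary(est)
    summary.to_csv(OUT / "parameter_recovery_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    n_sep = int(est["logit_separation"].sum())
    print(f"\nlogistic fits flagged for (quasi-)separation: {n_sep}/{REPS} "
          f"(sparse dizzy-and-fully-recovered cells at n = {N}; "
          f"the per-day coefficient is stable, median OR "
          f"{est['or_per_day'].median():.3f})")


if __name__ == "__main__":
    main()
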