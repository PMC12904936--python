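"""End-to-end analysis pipeline: filters -> scoring -> agreement -> prognosis.

``build_analysis_table`` turns scored patient records into the flat cohort
table every statistical stage consumes; ``run_pipeline`` chains all stages
and writes the report bundle (filter ledger, per-patient recovery, agreement
statistics, forest-plot tables, cohort summary).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import agreement, prognosis
from .audiometry import (
    MissingFrequencyError,
    classify_degree,
    classify_pattern,
    find_affected_runs,
    loss_profile,
    pta4,
    score_recovery,
)
from .filters import FilterConfig, FilterLedger, PatientRecord, apply_filters

__all__ = [
    "age_group",
    "build_analysis_table",
    "build_frequency_recovery_table",
    "table_one",
    "run_pipeline",
    "PipelineError",
]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and offending patient ids."""

    def __init__(self, stage: str, ids: Sequence[str], cause: Exception):
        self.stage = stage
        self.ids = list(ids)
        super().__init__(f"stage {stage!r} failed for {self.ids}: {cause}")


def age_group(age: float) -> str:
    """Young adults 18-39, middle-aged 40-59, older 60-69, elderly >= 70."""
    if age < 40:
        return "young"
    if age < 60:
        return "middle_aged"
    if age < 70:
        return "older"
    return "elderly"


def build_analysis_table(
    records: Sequence[PatientRecord],
    loss_reference: str = "interaural",
) -> pd.DataFrame:
    """Score every patient under both measures and assemble the cohort table.

    One row per patient with covariates, timing, both recovery measures
    (initial/follow-up/contralateral averages, recovery in dB, category) and
    the loss-pattern flags.  Flags are 0/1 integers for model fitting.
    """
    rows = []
    for rec in records:
        try:
            res_i = score_recovery(
                rec.diagnostic_affected, rec.followup_affected,
                rec.diagnostic_contralateral, "ipta", loss_reference=loss_reference,
            )
            res_p = score_recovery(
                rec.diagnostic_affected, rec.followup_affected,
                rec.diagnostic_contralateral, "pta4",
            )
            profile = loss_profile(rec.diagnostic_affected, rec.diagnostic_contralateral)
            runs = find_affected_runs(profile)
            pattern = classify_pattern(profile, runs)
            degree = classify_degree(pta4(rec.diagnostic_affected)).value
        except MissingFrequencyError as exc:
            raise PipelineError("scoring", [rec.id], exc) from exc
        rows.append(
            {
                "patient_id": rec.id,
                "age": rec.age,
                "age_group": age_group(rec.age),
                "female": int(rec.sex == "female"),
                "sex": rec.sex,
                "side": rec.side,
                "dizziness": int(rec.dizziness),
                "tinnitus": int(rec.tinnitus),
                "hypertension": int(rec.hypertension),
                "diabetes": int(rec.diabetes),
                "treatment": rec.treatment,
                "treated": int(rec.treated),
                "nonstandard_treatment": int(
                    rec.treatment in ("increased", "reduced", "intratympanic")
                ),
                "pretreated_before_audiogram": int(
                    (rec.treatment_before_audiogram_days or 0) > 0
                ),
                "identified_etiology": int(rec.later_identified_etiology is not None),
                "duration_days": rec.days_onset_to_assessment,
                "degree": degree,
                "range_specific": int(pattern.range_specific),
                "low_frequency": (None if pattern.low_frequency is None
                                  else int(pattern.low_frequency)),
                "high_frequency": int(pattern.high_frequency),
                "n_affected": len(res_i.frequencies),
                "initial_ipta": res_i.initial_value,
                "followup_ipta": res_i.followup_value,
                "contra_ipta": res_i.contralateral_value,
                "recovery_ipta": res_i.recovery_db,
                "category_ipta": res_i.category.value,
                "full_ipta": int(res_i.category.value == "full"),
                "partial_ipta": int(res_i.category.value == "partial"),
                "initial_pta4": res_p.initial_value,
                "followup_pta4": res_p.followup_value,
                "contra_pta4": res_p.contralateral_value,
                "recovery_pta4": res_p.recovery_db,
                "category_pta4": res_p.category.value,
                "full_pta4": int(res_p.category.value == "full"),
                "partial_pta4": int(res_p.category.value == "partial"),
                "prefilled_full_pta4": int(res_p.prefilled_full_at_diagnosis),
            }
        )
    return pd.DataFrame(rows)


def build_frequency_recovery_table(
    records: Sequence[PatientRecord],
    loss_reference: str = "interaural",
) -> pd.DataFrame:
    """Per-patient, per-affected-frequency recovery in dB (long format).

    Each frequency group contains only the patients for whom that frequency
    was affected; input for the one-way per-frequency ANOVA.
    """
    from .audiometry import absolute_loss_profile, affected_frequency_set

    rows = []
    for rec in records:
        if loss_reference == "absolute":
            profile = absolute_loss_profile(rec.diagnostic_affected)
        else:
            profile = loss_profile(rec.diagnostic_affected, rec.diagnostic_contralateral)
        freqs = affected_frequency_set(find_affected_runs(profile))
        for f in freqs:
            rows.append(
                {
                    "patient_id": rec.id,
                    "frequency": f,
                    "recovery_db": rec.diagnostic_affected[f] - rec.followup_affected[f],
                }
            )
    return pd.DataFrame(rows)


def table_one(table: pd.DataFrame) -> dict:
    """Cohort characteristics summary in the layout of a clinical Table 1."""
    def pct(col):
        return round(100.0 * table[col].mean(), 1)

    out = {
        "n": int(len(table)),
        "age_mean": round(float(table["age"].mean()), 1),
        "age_sd": round(float(table["age"].std(ddof=1)), 1),
        "age_groups_pct": {
            g: round(100.0 * (table["age_group"] == g).mean(), 1)
            for g in ("young", "middle_aged", "older", "elderly")
        },
        "female_pct": pct("female"),
        "hypertension_pct": pct("hypertension"),
        "diabetes_pct": pct("diabetes"),
        "tinnitus_pct": pct("tinnitus"),
        "dizziness_pct": pct("dizziness"),
        "treated_pct": pct("treated"),
        "initial_ipta_mean": round(float(table["initial_ipta"].mean()), 1),
        "initial_ipta_sd": round(float(table["initial_ipta"].std(ddof=1)), 1),
        "initial_pta4_mean": round(float(table["initial_pta4"].mean()), 1),
        "initial_pta4_sd": round(float(table["initial_pta4"].std(ddof=1)), 1),
        "degree_pct": {
            d: round(100.0 * (table["degree"] == d).mean(), 1)
            for d in ("no_mild", "moderate", "severe", "profound")
        },
        "range_specific_pct": pct("range_specific"),
        "duration_days_mean": round(float(table["duration_days"].mean()), 1),
        "duration_days_sd": round(float(table["duration_days"].std(ddof=1)), 1),
        "full_recovery_ipta_pct": pct("full_ipta"),
        "partial_recovery_ipta_pct": pct("partial_ipta"),
        "full_recovery_pta4_pct": pct("full_pta4"),
        "partial_recovery_pta4_pct": pct("partial_pta4"),
    }
    return out


def run_pipeline(
    records: Sequence[PatientRecord],
    outdir: str | Path,
    filter_config: Optional[FilterConfig] = None,
    seed: Optional[int] = None,
    loss_reference: str = "interaural",
    make_plots: bool = False,
    parse_failures: Optional[Sequence[tuple[str, str]]] = None,
) -> dict:
    """Filters -> scoring -> agreement -> prognostics -> sensitivity.

    Writes the report bundle under ``outdir`` and returns it as a dict:
    filter ledger, per-patient recovery table, Bland-Altman report,
    range-specific comparison, per-frequency ANOVA, forest-plot TSV of all
    regression models, and a Table-1-style cohort summary.  ``seed`` is
    logged in every report for provenance.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    included, ledger = apply_filters(records, filter_config, parse_failures)
    (outdir / "filter_ledger.json").write_text(ledger.to_json())
    (outdir / "flowchart.txt").write_text(ledger.to_text())

    table = build_analysis_table(included, loss_reference=loss_reference)
    table.to_csv(outdir / "recovery_table.csv", index=False)

    ba = agreement.bland_altman(table["recovery_ipta"], table["recovery_pta4"])
    rs = table[table["range_specific"] == 1]
    if len(rs) >= 2:
        rs_cmp = agreement.compare_measures_in_subgroup(
            rs["recovery_ipta"], rs["recovery_pta4"]
        ).__dict__
    else:
        rs_cmp = {"status": "not_applicable", "n": int(len(rs))}
    freq_table = build_frequency_recovery_table(included, loss_reference)
    anova = agreement.per_frequency_recovery_anova(freq_table)
    anova.posthoc.to_csv(outdir / "per_frequency_tukey.tsv", sep="\t", index=False)

    forest_frames = []
    fits = {}
    for measure in ("ipta", "pta4"):
        lin = prognosis.fit_linear_prognostic(table, prognosis.default_linear_spec(measure))
        logi_full = prognosis.fit_logistic_prognostic(
            table, prognosis.full_recovery_spec(measure))
        logi_partial = prognosis.fit_logistic_prognostic(
            table, prognosis.partial_vs_none_spec(measure))
        fits[measure] = {"linear": lin, "full": logi_full, "partial": logi_partial}
        forest_frames += [f.to_forest_frame() for f in fits[measure].values()]
    duration = prognosis.duration_subgroup_regressions(table)
    sensitivity = {}
    for rule in prognosis.SENSITIVITY_RULES:
        try:
            sensitivity[rule] = prognosis.sensitivity_analysis(table, rule)
            forest_frames.append(sensitivity[rule].to_forest_frame())
        except ValueError as exc:
            sensitivity[rule] = str(exc)
    forest = pd.concat(forest_frames, ignore_index=True)
    forest.to_csv(outdir / "forest.tsv", sep="\t", index=False)

    summary = {
        "seed": seed,
        "loss_reference": loss_reference,
        "n_assessed": ledger.n_initial,
        "n_included": ledger.n_final,
        "table_one": table_one(table),
        "bland_altman": ba.to_dict(),
        "range_specific_comparison": rs_cmp,
        "per_frequency_anova": {"F": anova.f, "p": anova.p,
                                "group_means": {str(k): v for k, v in
                                                anova.group_means.items()}},
        "duration_subgroups": {
            arm: {
                kind: {
                    "slope": float(fit.coefficient("duration_days")["estimate"]),
                    "ci_low": float(fit.coefficient("duration_days")["ci_low"]),
                    "ci_high": float(fit.coefficient("duration_days")["ci_high"]),
                    "p": float(fit.coefficient("duration_days")["p"]),
                }
                for kind, fit in arms.items()
            }
            for arm, arms in duration.items()
        },
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))

    if make_plots:
        agreement.bland_altman_plot(
            ba, table["recovery_ipta"], table["recovery_pta4"],
            outdir / "bland_altman.png",
        )

    return {
        "ledger": ledger,
        "table": table,
        "bland_altman": ba,
        "range_specific": rs_cmp,
        "anova": anova,
        "fits": fits,
        "duration": duration,
        "sensitivity": sensitivity,
        "summary": summary,
    }
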