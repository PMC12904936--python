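"""Cohort CSV schema and typed reading/writing.

One row per patient per timepoint (``diagnostic`` or ``followup``).
Covariate and timing columns are repeated on both rows of a patient and are
taken from the diagnostic row.  Threshold columns hold air conduction for
the affected (``ac_aff_<freq>``) and contralateral (``ac_contra_<freq>``)
ears at every grid frequency, plus optional bone conduction for the affected
ear (``bc_aff_<freq>``, 500-4000 Hz, diagnostic row only).  A blank cell
means the frequency was not measured.  Thresholds must parse to multiples of
5 dB in [-10, 120].  Every patient must have a diagnostic row; a follow-up
row is optional (its absence means lost to audiometric follow-up).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .audiometry import BONE_FREQUENCIES, FREQUENCIES, AudiometryError, EarThresholds
from .filters import PatientRecord

__all__ = ["COLUMNS", "ParseReport", "read_cohort", "write_cohort"]

_COVARIATE_COLUMNS = (
    "patient_id", "timepoint", "age", "sex", "side",
    "dizziness", "tinnitus", "hypertension", "diabetes",
    "treatment", "onset_known", "onset_within_72h",
    "days_onset_to_assessment", "days_onset_to_treatment",
    "treatment_before_audiogram_days", "preknown_cause",
    "later_identified_etiology",
)

#: Exact CSV header, in order.
COLUMNS: tuple[str, ...] = (
    *_COVARIATE_COLUMNS,
    *(f"ac_aff_{f}" for f in FREQUENCIES),
    *(f"ac_contra_{f}" for f in FREQUENCIES),
    *(f"bc_aff_{f}" for f in BONE_FREQUENCIES),
)


@dataclass
class ParseReport:
    """Rows that could not be parsed, with reasons; never silently dropped."""

    failures: list[tuple[str, str]] = field(default_factory=list)

    def add(self, patient_id: str, reason: str) -> None:
        self.failures.append((patient_id, reason))

    def __len__(self) -> int:
        return len(self.failures)


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float) and value == int(value):
        return str(int(value))
    return str(value)


def _ear_cells(ear: Optional[EarThresholds], prefix: str, freqs) -> dict[str, str]:
    cells = {}
    for f in freqs:
        v = ear[f] if (ear is not None and f in ear) else None
        cells[f"{prefix}_{f}"] = _fmt(v)
    return cells


def write_cohort(records: Sequence[PatientRecord], path: str | Path) -> None:
    """Write records to the cohort CSV schema (diagnostic + follow-up rows)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=COLUMNS)
        w.writeheader()
        for rec in records:
            base = {
                "patient_id": rec.id,
                "age": _fmt(rec.age),
                "sex": rec.sex,
                "side": rec.side,
                "dizziness": _fmt(rec.dizziness),
                "tinnitus": _fmt(rec.tinnitus),
                "hypertension": _fmt(rec.hypertension),
                "diabetes": _fmt(rec.diabetes),
                "treatment": rec.treatment,
                "onset_known": _fmt(rec.onset_known),
                "onset_within_72h": _fmt(rec.onset_within_72h),
                "days_onset_to_assessment": _fmt(rec.days_onset_to_assessment),
                "days_onset_to_treatment": _fmt(rec.days_onset_to_treatment),
                "treatment_before_audiogram_days": _fmt(rec.treatment_before_audiogram_days),
                "preknown_cause": _fmt(rec.preknown_cause),
                "later_identified_etiology": _fmt(rec.later_identified_etiology),
            }
            diag = dict(base)
            diag["timepoint"] = "diagnostic"
            diag.update(_ear_cells(rec.diagnostic_affected, "ac_aff", FREQUENCIES))
            diag.update(_ear_cells(rec.diagnostic_contralateral, "ac_contra", FREQUENCIES))
            diag.update(_ear_cells(rec.diagnostic_bone, "bc_aff", BONE_FREQUENCIES))
            w.writerow(diag)
            if rec.followup_affected is not None or rec.followup_contralateral is not None:
                fu = dict(base)
                fu["timepoint"] = "followup"
                fu.update(_ear_cells(rec.followup_affected, "ac_aff", FREQUENCIES))
                fu.update(_ear_cells(rec.followup_contralateral, "ac_contra", FREQUENCIES))
                fu.update({f"bc_aff_{f}": "" for f in BONE_FREQUENCIES})
                w.writerow(fu)


def _parse_thresholds(row: dict, prefix: str, freqs) -> Optional[dict[int, float]]:
    out = {}
    for f in freqs:
        cell = (row.get(f"{prefix}_{f}") or "").strip()
        if not cell:
            continue
        v = float(cell)
        if v % 5 != 0:
            raise ValueError(f"{prefix}_{f} = {cell!r} is not a 5 dB step")
        out[f] = v
    return out or None


def _parse_bool(cell: str, default: bool = False) -> bool:
    cell = (cell or "").strip().lower()
    if cell in ("", "na"):
        return default
    if cell in ("1", "true", "yes"):
        return True
    if cell in ("0", "false", "no"):
        return False
    raise ValueError(f"not a boolean: {cell!r}")


def _opt_float(cell: str) -> Optional[float]:
    cell = (cell or "").strip()
    return float(cell) if cell else None


def read_cohort(path: str | Path) -> tuple[list[PatientRecord], ParseReport]:
    """Parse a cohort CSV into typed patient records.

    Unknown or missing header columns and duplicated (patient, timepoint)
    pairs are hard errors.  Rows that fail value-level parsing are collected
    into the returned :class:`ParseReport` (feed it to ``apply_filters`` so
    the rejects are ledgered).
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = tuple(reader.fieldnames or ())
        if header != COLUMNS:
            unknown = set(header) - set(COLUMNS)
            missing = set(COLUMNS) - set(header)
            raise ValueError(
                f"cohort CSV header mismatch: unknown columns {sorted(unknown)}, "
                f"missing columns {sorted(missing)}"
            )
        rows = list(reader)

    seen: set[tuple[str, str]] = set()
    by_patient: dict[str, dict[str, dict]] = {}
    order: list[str] = []
    for row in rows:
        pid = row["patient_id"].strip()
        tp = row["timepoint"].strip()
        if tp not in ("diagnostic", "followup"):
            raise ValueError(f"patient {pid}: invalid timepoint {tp!r}")
        if (pid, tp) in seen:
            raise ValueError(f"duplicated (patient, timepoint): ({pid}, {tp})")
        seen.add((pid, tp))
        if pid not in by_patient:
            order.append(pid)
        by_patient.setdefault(pid, {})[tp] = row

    records: list[PatientRecord] = []
    report = ParseReport()
    for pid in order:
        tps = by_patient[pid]
        if "diagnostic" not in tps:
            report.add(pid, "no diagnostic row")
            continue
        diag, fu = tps["diagnostic"], tps.get("followup")
        try:
            side = diag["side"].strip()
            contra_side = "left" if side == "right" else "right"

            def ear(row, prefix, side_, conduction="air", freqs=FREQUENCIES):
                thr = _parse_thresholds(row, prefix, freqs)
                if thr is None:
                    return None
                return EarThresholds(thr, side=side_, conduction=conduction)

            records.append(
                PatientRecord(
                    id=pid,
                    age=float(diag["age"]),
                    sex=diag["sex"].strip(),
                    side=side,
                    onset_known=_parse_bool(diag["onset_known"], True),
                    onset_within_72h=_parse_bool(diag["onset_within_72h"], True),
                    days_onset_to_assessment=float(diag["days_onset_to_assessment"] or 0),
                    days_onset_to_treatment=_opt_float(diag["days_onset_to_treatment"]),
                    treatment=diag["treatment"].strip() or "none",
                    treatment_before_audiogram_days=_opt_float(
                        diag["treatment_before_audiogram_days"]),
                    hypertension=_parse_bool(diag["hypertension"]),
                    diabetes=_parse_bool(diag["diabetes"]),
                    tinnitus=_parse_bool(diag["tinnitus"]),
                    dizziness=_parse_bool(diag["dizziness"]),
                    preknown_cause=_parse_bool(diag["preknown_cause"]),
                    later_identified_etiology=(diag["later_identified_etiology"].strip()
                                               or None),
                    diagnostic_affected=ear(diag, "ac_aff", side),
                    diagnostic_contralateral=ear(diag, "ac_contra", contra_side),
                    diagnostic_bone=ear(diag, "bc_aff", side, "bone", BONE_FREQUENCIES),
                    followup_affected=ear(fu, "ac_aff", side) if fu else None,
                    followup_contralateral=ear(fu, "ac_contra", contra_side) if fu else None,
                )
            )
        except (ValueError, AudiometryError) as exc:
            report.add(pid, str(exc))
    return records, report
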