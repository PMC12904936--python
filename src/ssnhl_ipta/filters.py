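"""Cohort inclusion/exclusion pipeline with an auditable flowchart ledger.

The study population is defined by the SSNHL diagnostic criterion plus a set
of exclusion rules applied to a retrospective cohort.  ``apply_filters`` runs
the rules in a fixed order and records, per rule, how many patients (and
which) it removed, so the result can be rendered as a study flowchart and the
counts audited: n_in - sum(excluded) == n_out, and every excluded id appears
exactly once with a reason.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

from .audiometry import (
    EarThresholds,
    absolute_loss_profile,
    conductive_check,
    find_affected_runs,
    loss_profile,
)

__all__ = ["PatientRecord", "FilterConfig", "FilterLedger", "apply_filters", "FILTER_STEPS"]


@dataclass
class PatientRecord:
    """One patient: covariates, timing, treatment and audiograms.

    ``days_onset_to_assessment`` is the disease duration until assessment:
    days from hearing-loss onset to treatment start, or to the diagnostic
    audiogram if no treatment was given.
    """

    id: str
    age: float
    sex: str                       # "female" | "male"
    side: str                      # affected side, "left" | "right"
    onset_known: bool = True
    onset_within_72h: bool = True
    days_onset_to_assessment: float = 0.0
    days_onset_to_treatment: Optional[float] = None
    treatment: str = "none"        # standard | increased | reduced | intratympanic | none
    treatment_before_audiogram_days: Optional[float] = None
    hypertension: bool = False
    diabetes: bool = False
    tinnitus: bool = False
    dizziness: bool = False        # within a day of onset
    preknown_cause: bool = False
    later_identified_etiology: Optional[str] = None
    diagnostic_affected: Optional[EarThresholds] = None
    diagnostic_contralateral: Optional[EarThresholds] = None
    diagnostic_bone: Optional[EarThresholds] = None
    followup_affected: Optional[EarThresholds] = None
    followup_contralateral: Optional[EarThresholds] = None

    def __post_init__(self):
        if self.age < 0:
            raise ValueError(f"patient {self.id}: negative age")
        if self.days_onset_to_assessment < 0:
            raise ValueError(f"patient {self.id}: negative day count")

    @property
    def treated(self) -> bool:
        return self.treatment != "none"


@dataclass
class FilterConfig:
    """Thresholds of the inclusion/exclusion rules."""

    loss_threshold_db: float = 30.0
    min_consecutive: int = 3
    onset_window_hours: float = 72.0
    max_days_to_assessment: float = 30.0
    max_treatment_before_audiogram_days: float = 3.0
    min_age_years: float = 18.0
    air_bone_gap_db: float = 10.0
    loss_reference: str = "interaural"   # or "absolute"
    strict_grid: bool = False


@dataclass
class FilterLedger:
    """Ordered per-rule exclusion counts, flowchart style."""

    n_initial: int = 0
    steps: list[dict] = field(default_factory=list)

    def record(self, name: str, excluded_ids: Sequence[str], n_before: int) -> None:
        self.steps.append(
            {
                "filter": name,
                "n_excluded": len(excluded_ids),
                "excluded_ids": list(excluded_ids),
                "n_remaining": n_before - len(excluded_ids),
            }
        )

    @property
    def n_final(self) -> int:
        return self.steps[-1]["n_remaining"] if self.steps else self.n_initial

    @property
    def n_excluded_total(self) -> int:
        return sum(s["n_excluded"] for s in self.steps)

    def check_conservation(self) -> bool:
        return self.n_initial - self.n_excluded_total == self.n_final

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(
            {"n_initial": self.n_initial, "steps": self.steps, "n_final": self.n_final},
            indent=indent,
        )

    def to_text(self) -> str:
        """Plain-text study flowchart."""
        lines = [f"Assessed for eligibility: n = {self.n_initial}"]
        for s in self.steps:
            lines.append(f"  |-- excluded: {s['filter']} (n = {s['n_excluded']})")
            lines.append(f"  v   remaining: n = {s['n_remaining']}")
        lines.append(f"Included: n = {self.n_final}")
        return "\n".join(lines)


def _meets_main_criterion(rec: PatientRecord, cfg: FilterConfig) -> bool:
    """>= 30 dB loss at >= 3 consecutive frequencies, onset within 72 h."""
    if not rec.onset_within_72h:
        return False
    if rec.diagnostic_affected is None:
        return True  # cannot evaluate: handled by the missing-audiogram rule
    try:
        if cfg.loss_reference == "absolute":
            profile = absolute_loss_profile(rec.diagnostic_affected)
        else:
            if rec.diagnostic_contralateral is None:
                return True
            profile = loss_profile(rec.diagnostic_affected, rec.diagnostic_contralateral)
        runs = find_affected_runs(
            profile, cfg.loss_threshold_db, cfg.min_consecutive, cfg.strict_grid
        )
    except ValueError:
        return True
    return bool(runs)


# (name, predicate returning True when the record is EXCLUDED by this rule)
FILTER_STEPS: list[tuple[str, Callable[[PatientRecord, FilterConfig], bool]]] = [
    (
        "not_meeting_ssnhl_criterion",
        lambda r, c: not _meets_main_criterion(r, c),
    ),
    (
        "undeterminable_onset_or_assessment_delayed",
        lambda r, c: (not r.onset_known) or r.days_onset_to_assessment > c.max_days_to_assessment,
    ),
    (
        "primarily_conductive_hl",
        lambda r, c: r.diagnostic_affected is not None
        and conductive_check(r.diagnostic_affected, r.diagnostic_bone, c.air_bone_gap_db),
    ),
    (
        "preknown_cause_of_hl",
        lambda r, c: r.preknown_cause,
    ),
    (
        "treatment_started_before_audiogram",
        lambda r, c: r.treatment_before_audiogram_days is not None
        and r.treatment_before_audiogram_days > c.max_treatment_before_audiogram_days,
    ),
    (
        "no_initial_audiogram_or_lost_to_followup",
        lambda r, c: r.diagnostic_affected is None
        or r.diagnostic_contralateral is None
        or r.followup_affected is None,
    ),
    (
        "age_under_18",
        lambda r, c: r.age < c.min_age_years,
    ),
]


def apply_filters(
    records: Sequence[PatientRecord],
    config: Optional[FilterConfig] = None,
    parse_failures: Optional[Sequence[tuple[str, str]]] = None,
) -> tuple[list[PatientRecord], FilterLedger]:
    """Run the inclusion/exclusion pipeline.

    ``parse_failures`` are (id, reason) pairs of records that could not be
    parsed upstream; they are ledgered as an initial rejection step rather
    than silently dropped.  Each surviving record is evaluated rule by rule;
    a record is excluded by the *first* rule it violates, so every excluded
    id carries exactly one reason.
    """
    config = config or FilterConfig()
    parse_failures = list(parse_failures or [])
    ledger = FilterLedger(n_initial=len(records) + len(parse_failures))
    remaining = list(records)
    if parse_failures:
        ledger.record(
            "parse_error", [pid for pid, _ in parse_failures], ledger.n_initial
        )
    for name, excludes in FILTER_STEPS:
        kept, dropped = [], []
        for rec in remaining:
            (dropped if excludes(rec, config) else kept).append(rec)
        ledger.record(name, [r.id for r in dropped], len(remaining))
        remaining = kept
    assert ledger.check_conservation()
    return remaining, ledger
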