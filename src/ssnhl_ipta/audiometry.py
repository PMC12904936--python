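"""Audiometric scoring for sudden sensorineural hearing loss (SSNHL).

The diagnostic criterion for SSNHL is >= 30 dB hearing loss (HL) over at
least three consecutive audiometric frequencies arising within 72 h.  This
module implements the scoring primitives built on that criterion:

* interaural loss profiles (affected ear referenced to the contralateral ear),
* detection of maximal runs of consecutive affected frequencies,
* the conventional four-frequency pure-tone average (PTA4: 500, 1000, 2000,
  4000 Hz) and the *individual* pure-tone average (iPTA) taken over exactly
  the patient's consecutive affected frequencies,
* WHO degree-of-HL classes, low/high/range-specific loss patterns,
* the full / partial / no recovery taxonomy, and
* the air-bone-gap screen for primarily conductive loss.

Hearing levels are in dB HL on the standard clinical grid and are recorded in
5 dB steps.  By default, consecutiveness is evaluated over the *measured*
frequencies in grid order: a frequency that was not tested neither counts as
affected nor splits a run (routine clinical audiograms often skip 125, 1500,
3000 or 8000 Hz).  A strict-grid mode is available where unmeasured
frequencies break runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

__all__ = [
    "FREQUENCIES",
    "PTA4_FREQUENCIES",
    "ALWAYS_MEASURED",
    "BONE_FREQUENCIES",
    "AudiometryError",
    "MissingFrequencyError",
    "NoAffectedRunError",
    "EarThresholds",
    "AffectedRun",
    "DegreeClass",
    "FrequencyPattern",
    "RecoveryCategory",
    "RecoveryResult",
    "pta4",
    "loss_profile",
    "find_affected_runs",
    "affected_frequency_set",
    "ipta",
    "classify_degree",
    "classify_pattern",
    "score_recovery",
    "conductive_check",
]

#: The standard audiometric frequency grid (Hz).
FREQUENCIES: tuple[int, ...] = (125, 250, 500, 1000, 1500, 2000, 3000, 4000, 6000, 8000)

#: Frequencies entering the conventional four-frequency pure-tone average.
PTA4_FREQUENCIES: tuple[int, ...] = (500, 1000, 2000, 4000)

#: Frequencies measured on every clinical audiogram in this setting.
ALWAYS_MEASURED: tuple[int, ...] = (500, 1000, 2000, 4000, 6000)

#: Frequencies on which bone conduction is routinely measured.
BONE_FREQUENCIES: tuple[int, ...] = (500, 1000, 2000, 4000)

_GRID_INDEX = {f: i for i, f in enumerate(FREQUENCIES)}

MIN_THRESHOLD_DB = -10.0
MAX_THRESHOLD_DB = 120.0  # no-response thresholds are clipped here
THRESHOLD_STEP_DB = 5.0


class AudiometryError(ValueError):
    """Base class for audiometric scoring errors."""


class MissingFrequencyError(AudiometryError):
    """A threshold required by the requested computation was not measured."""

    def __init__(self, frequency: int, context: str = ""):
        self.frequency = frequency
        msg = f"missing threshold at {frequency} Hz"
        if context:
            msg += f" ({context})"
        super().__init__(msg)


class NoAffectedRunError(AudiometryError):
    """The audiogram has no qualifying run: the SSNHL criterion is not met."""


@dataclass(frozen=True)
class EarThresholds:
    """Pure-tone thresholds for one ear at one timepoint.

    Parameters
    ----------
    thresholds
        Partial map frequency (Hz) -> hearing level (dB HL).  Only grid
        frequencies are allowed; values must be multiples of 5 dB within
        [-10, 120] dB HL.
    side
        ``"left"`` or ``"right"``.
    conduction
        ``"air"`` or ``"bone"``.
    """

    thresholds: Mapping[int, float]
    side: str = "right"
    conduction: str = "air"

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise AudiometryError(f"invalid side: {self.side!r}")
        if self.conduction not in ("air", "bone"):
            raise AudiometryError(f"invalid conduction: {self.conduction!r}")
        clean: dict[int, float] = {}
        for f in sorted(self.thresholds, key=lambda f: _GRID_INDEX.get(f, -1)):
            v = self.thresholds[f]
            if f not in _GRID_INDEX:
                raise AudiometryError(f"frequency {f} Hz not on the audiometric grid")
            v = float(v)
            if not (MIN_THRESHOLD_DB <= v <= MAX_THRESHOLD_DB):
                raise AudiometryError(f"threshold {v} dB HL at {f} Hz outside [-10, 120]")
            if v % THRESHOLD_STEP_DB != 0:
                raise AudiometryError(f"threshold {v} dB HL at {f} Hz is not a 5 dB step")
            clean[f] = v
        object.__setattr__(self, "thresholds", clean)

    def __getitem__(self, frequency: int) -> float:
        try:
            return self.thresholds[frequency]
        except KeyError:
            raise MissingFrequencyError(frequency, f"{self.side} ear, {self.conduction}")

    def __contains__(self, frequency: int) -> bool:
        return frequency in self.thresholds

    @property
    def frequencies(self) -> tuple[int, ...]:
        """Measured frequencies in ascending grid order."""
        return tuple(self.thresholds)

    def mean_over(self, frequencies: Sequence[int]) -> float:
        """Arithmetic mean threshold over ``frequencies`` (all must be measured)."""
        if not frequencies:
            raise AudiometryError("cannot average over an empty frequency set")
        return sum(self[f] for f in frequencies) / len(frequencies)


@dataclass(frozen=True)
class AffectedRun:
    """A maximal run of consecutive frequencies with qualifying hearing loss."""

    frequencies: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.frequencies)

    def __iter__(self):
        return iter(self.frequencies)


class DegreeClass(str, Enum):
    """WHO degree of hearing loss, from the affected ear's PTA4 in dB."""

    NO_MILD = "no_mild"      # <= 40 dB
    MODERATE = "moderate"    # 41-60 dB
    SEVERE = "severe"        # 61-80 dB
    PROFOUND = "profound"    # > 80 dB

    @property
    def rank(self) -> int:
        return ("no_mild", "moderate", "severe", "profound").index(self.value)


class RecoveryCategory(str, Enum):
    FULL = "full"
    PARTIAL = "partial"
    NONE = "none"


@dataclass(frozen=True)
class FrequencyPattern:
    """Loss-pattern flags for one diagnostic loss profile.

    ``low_frequency`` is ``None`` (indeterminate) when 125, 250 or 500 Hz was
    not measured on both ears, since the definition cannot be evaluated.
    """

    low_frequency: Optional[bool]
    high_frequency: bool
    range_specific: bool


@dataclass(frozen=True)
class RecoveryResult:
    """Recovery of one patient under one measure (iPTA or PTA4).

    ``recovery_db`` is initial minus follow-up (positive = improvement).
    ``category`` follows the guideline taxonomy: *full* when the follow-up
    average returns to within 10 dB of the contralateral ear over the same
    frequencies; otherwise *partial* when the improvement exceeds 10 dB and
    *none* when it does not.  Worsening (negative recovery) is *none*.
    """

    measure: str
    frequencies: tuple[int, ...]
    initial_value: float
    followup_value: float
    contralateral_value: float
    recovery_db: float
    category: RecoveryCategory
    prefilled_full_at_diagnosis: bool = False


def pta4(ear: EarThresholds) -> float:
    """Four-frequency pure-tone average (500, 1000, 2000, 4000 Hz), unrounded."""
    return ear.mean_over(PTA4_FREQUENCIES)


def loss_profile(affected: EarThresholds, contralateral: EarThresholds) -> dict[int, float]:
    """Per-frequency interaural loss: affected minus contralateral threshold.

    Defined on the intersection of measured frequencies; values may be
    negative where the affected ear hears better.
    """
    if affected.conduction != contralateral.conduction:
        raise AudiometryError("ears have different conduction types")
    if affected.side == contralateral.side:
        raise AudiometryError("affected and contralateral ears are the same side")
    common = [f for f in FREQUENCIES if f in affected and f in contralateral]
    if not common:
        raise AudiometryError("no frequency measured on both ears")
    return {f: affected[f] - contralateral[f] for f in common}


def absolute_loss_profile(affected: EarThresholds) -> dict[int, float]:
    """Loss referenced to 0 dB HL rather than the contralateral ear.

    Alternative mode for the >= 30 dB criterion when the contralateral ear is
    an unreliable baseline.
    """
    return {f: affected[f] for f in affected.frequencies}


def find_affected_runs(
    profile: Mapping[int, float],
    loss_threshold: float = 30.0,
    min_len: int = 3,
    strict_grid: bool = False,
) -> list[AffectedRun]:
    """All maximal runs of consecutive affected frequencies.

    A frequency is *affected* when its loss is >= ``loss_threshold``.  Runs
    are maximal blocks of consecutive frequencies, where consecutive means
    adjacent among the *measured* frequencies in grid order (default) or
    adjacent on the full grid (``strict_grid=True``, unmeasured frequencies
    split runs).  Only runs of at least ``min_len`` qualify.  An empty result
    is valid: the profile does not meet the SSNHL criterion.
    """
    if not profile:
        raise AudiometryError("empty loss profile")
    measured = sorted(profile, key=_GRID_INDEX.__getitem__)
    runs: list[AffectedRun] = []
    current: list[int] = []
    prev_idx: Optional[int] = None
    for f in measured:
        idx = _GRID_INDEX[f]
        contiguous = prev_idx is not None and (idx == prev_idx + 1 or not strict_grid)
        if profile[f] >= loss_threshold:
            if current and not contiguous:
                if len(current) >= min_len:
                    runs.append(AffectedRun(tuple(current)))
                current = []
            current.append(f)
        else:
            if len(current) >= min_len:
                runs.append(AffectedRun(tuple(current)))
            current = []
        prev_idx = idx
    if len(current) >= min_len:
        runs.append(AffectedRun(tuple(current)))
    return runs


def affected_frequency_set(runs: Sequence[AffectedRun]) -> tuple[int, ...]:
    """Union of all qualifying runs' frequencies, in ascending order.

    This is the frequency set over which the iPTA is computed: *all*
    consecutive affected frequencies, not only the longest run.
    """
    freqs = {f for run in runs for f in run}
    return tuple(sorted(freqs, key=_GRID_INDEX.__getitem__))


def ipta(ear: EarThresholds, frequencies: Sequence[int]) -> float:
    """Individual pure-tone average over the given affected-frequency set."""
    if not frequencies:
        raise NoAffectedRunError(
            "empty affected-frequency set: the SSNHL criterion "
            "(>= 30 dB loss at >= 3 consecutive frequencies) is not met"
        )
    return ear.mean_over(frequencies)


def classify_degree(pta4_value: float) -> DegreeClass:
    """WHO degree class from PTA4 in dB.

    Boundaries: no/mild <= 40 < moderate <= 60 < severe <= 80 < profound.
    With 5 dB-step audiometry PTA4 is a multiple of 1.25, so the > 80 rule
    and the tabulated ">= 81" rule coincide.
    """
    if not (pta4_value == pta4_value):  # NaN guard
        raise AudiometryError("PTA4 is not a finite number")
    if pta4_value <= 40:
        return DegreeClass.NO_MILD
    if pta4_value <= 60:
        return DegreeClass.MODERATE
    if pta4_value <= 80:
        return DegreeClass.SEVERE
    return DegreeClass.PROFOUND


_LOW_FREQS = (125, 250, 500)
_HIGH_FREQS = (3000, 4000, 6000, 8000)


def classify_pattern(
    profile: Mapping[int, float],
    runs: Optional[Sequence[AffectedRun]] = None,
    loss_threshold: float = 30.0,
    min_len: int = 3,
) -> FrequencyPattern:
    """Loss-pattern flags for a diagnostic loss profile.

    * low-frequency HL: loss >= threshold at 125, 250 and 500 Hz
      (indeterminate when 125 or 250 Hz was unmeasured);
    * high-frequency HL: a qualifying run of >= ``min_len`` consecutive
      measured frequencies lying entirely within 3000-8000 Hz;
    * range-specific HL: exactly 3 or 4 affected frequencies in total, all
      forming a single qualifying run, with loss < threshold everywhere else
      measured.
    """
    if runs is None:
        runs = find_affected_runs(profile, loss_threshold, min_len)
    affected = [f for f in profile if profile[f] >= loss_threshold]

    if any(f not in profile for f in _LOW_FREQS):
        low: Optional[bool] = None
    else:
        low = all(profile[f] >= loss_threshold for f in _LOW_FREQS)

    high_profile = {f: v for f, v in profile.items() if f in _HIGH_FREQS}
    high = False
    if high_profile:
        high = any(
            len(run) >= min_len
            for run in find_affected_runs(high_profile, loss_threshold, min_len)
        )

    range_specific = (
        len(runs) == 1
        and len(runs[0]) == len(affected)
        and len(affected) in (3, 4)
    )
    return FrequencyPattern(low_frequency=low, high_frequency=high, range_specific=range_specific)


def score_recovery(
    initial: EarThresholds,
    followup: EarThresholds,
    contralateral: EarThresholds,
    measure: str = "ipta",
    loss_threshold: float = 30.0,
    min_len: int = 3,
    full_margin_db: float = 10.0,
    partial_margin_db: float = 10.0,
    loss_reference: str = "interaural",
) -> RecoveryResult:
    """Score one patient's hearing recovery under iPTA or PTA4.

    For iPTA, the affected-frequency set is determined from the *diagnostic*
    audiogram and reused verbatim at follow-up, and the contralateral value
    is the contralateral ear averaged over that same set.  For PTA4 all three
    values are plain PTA4s.  *Full* recovery: follow-up average within
    ``full_margin_db`` of the contralateral value; *partial*: improvement
    greater than ``partial_margin_db`` without meeting the full criterion;
    *none* otherwise.  ``prefilled_full_at_diagnosis`` flags cases where the
    full-recovery criterion already held on the diagnostic audiogram (possible
    under PTA4 when the lesion misses the PTA4 frequencies).
    """
    measure = measure.lower()
    if measure == "ipta":
        if loss_reference == "interaural":
            profile = loss_profile(initial, contralateral)
        elif loss_reference == "absolute":
            profile = absolute_loss_profile(initial)
        else:
            raise AudiometryError(f"unknown loss reference: {loss_reference!r}")
        runs = find_affected_runs(profile, loss_threshold, min_len)
        freqs = affected_frequency_set(runs)
        if not freqs:
            raise NoAffectedRunError(
                "diagnostic audiogram has no qualifying affected run; "
                "the patient does not meet the SSNHL criterion"
            )
        initial_value = ipta(initial, freqs)
        followup_value = ipta(followup, freqs)
        contralateral_value = ipta(contralateral, freqs)
    elif measure == "pta4":
        freqs = PTA4_FREQUENCIES
        initial_value = pta4(initial)
        followup_value = pta4(followup)
        contralateral_value = pta4(contralateral)
    else:
        raise AudiometryError(f"unknown measure: {measure!r} (expected 'ipta' or 'pta4')")

    recovery_db = initial_value - followup_value
    if followup_value - contralateral_value <= full_margin_db:
        category = RecoveryCategory.FULL
    elif recovery_db > partial_margin_db:
        category = RecoveryCategory.PARTIAL
    else:
        category = RecoveryCategory.NONE
    prefilled = initial_value - contralateral_value <= full_margin_db
    return RecoveryResult(
        measure=measure,
        frequencies=tuple(freqs),
        initial_value=initial_value,
        followup_value=followup_value,
        contralateral_value=contralateral_value,
        recovery_db=recovery_db,
        category=category,
        prefilled_full_at_diagnosis=prefilled,
    )


def conductive_check(
    air: EarThresholds,
    bone: Optional[EarThresholds],
    gap_threshold_db: float = 10.0,
) -> bool:
    """Screen for primarily conductive hearing loss on the diagnostic audiogram.

    Returns ``True`` (exclude: primarily conductive) when the air-bone gap in
    PTA4 exceeds ``gap_threshold_db``.  With no usable bone-conduction data
    the check is skipped with a warning and ``False`` is returned, matching
    retrospective chart review where bone conduction is often unavailable.
    """
    if bone is None:
        warnings.warn("no bone-conduction data: conductive check skipped", stacklevel=2)
        return False
    try:
        bone_avg = bone.mean_over(BONE_FREQUENCIES)
    except MissingFrequencyError as exc:
        warnings.warn(f"incomplete bone-conduction data ({exc}): conductive check skipped",
                      stacklevel=2)
        return False
    return pta4(air) - bone_avg > gap_threshold_db
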