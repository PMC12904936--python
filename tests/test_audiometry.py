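"""Audiometric scoring: PTA4, iPTA, run detection, taxonomy, patterns."""

import numpy as np
import pytest

from ssnhl_ipta.audiometry import (
    FREQUENCIES,
    PTA4_FREQUENCIES,
    AudiometryError,
    DegreeClass,
    EarThresholds,
    MissingFrequencyError,
    NoAffectedRunError,
    RecoveryCategory,
    affected_frequency_set,
    classify_degree,
    classify_pattern,
    conductive_check,
    find_affected_runs,
    ipta,
    loss_profile,
    pta4,
    score_recovery,
)
from helpers import ear


def flat(level, freqs=FREQUENCIES, **kw):
    return ear({f: level for f in freqs}, **kw)


class TestEarThresholds:
    def test_rejects_off_grid_frequency(self):
        with pytest.raises(AudiometryError, match="not on the audiometric grid"):
            ear({750: 30})

    @pytest.mark.parametrize("value", [37, -15, 125])
    def test_rejects_invalid_levels(self, value):
        with pytest.raises(AudiometryError):
            ear({500: value})

    def test_missing_frequency_error_names_frequency(self):
        with pytest.raises(MissingFrequencyError, match="1500 Hz"):
            ear({500: 30})[1500]


class TestPta4:
    @pytest.mark.parametrize(
        "thresholds,expected",
        [
            ({500: 50, 1000: 60, 2000: 70, 4000: 80}, 65.0),
            ({500: 0, 1000: 0, 2000: 0, 4000: 0}, 0.0),
            ({500: 35, 1000: 45, 2000: 50, 4000: 55}, 46.25),
        ],
    )
    def test_arithmetic_mean(self, thresholds, expected):
        assert pta4(ear(thresholds)) == pytest.approx(expected)

    def test_missing_frequency_raises(self):
        with pytest.raises(MissingFrequencyError, match="2000 Hz"):
            pta4(ear({500: 50, 1000: 60, 4000: 80}))

    def test_ipta_over_pta4_frequencies_equals_pta4(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            e = ear({f: 5 * rng.integers(0, 20) for f in FREQUENCIES})
            assert ipta(e, PTA4_FREQUENCIES) == pta4(e)


class TestLossProfile:
    def test_subtraction_and_sign(self):
        aff = ear({1000: 70, 8000: 20}, side="right")
        contra = ear({1000: 20, 8000: 30}, side="left")
        assert loss_profile(aff, contra) == {1000: 50, 8000: -10}

    def test_identical_ears_give_zero_profile(self):
        aff, contra = flat(40, side="right"), flat(40, side="left")
        assert set(loss_profile(aff, contra).values()) == {0.0}

    def test_defined_on_intersection_only(self):
        aff = ear({500: 70, 1000: 70}, side="right")
        contra = ear({1000: 10, 2000: 10}, side="left")
        assert loss_profile(aff, contra) == {1000: 60}

    def test_same_side_rejected(self):
        with pytest.raises(AudiometryError, match="same side"):
            loss_profile(flat(40, side="left"), flat(10, side="left"))

    def test_empty_intersection_rejected(self):
        with pytest.raises(AudiometryError, match="no frequency"):
            loss_profile(ear({500: 70}, side="right"), ear({8000: 10}, side="left"))


def brute_force_runs(profile, threshold=30, min_len=3, strict=False):
    """Oracle: enumerate all contiguous subsequences, keep maximal affected ones."""
    order = {f: i for i, f in enumerate(FREQUENCIES)}
    measured = sorted(profile, key=order.get)
    if strict:
        # split measured list wherever the grid has an unmeasured hole
        blocks, cur = [], [measured[0]]
        for a, b in zip(measured, measured[1:]):
            if order[b] == order[a] + 1:
                cur.append(b)
            else:
                blocks.append(cur)
                cur = [b]
        blocks.append(cur)
    else:
        blocks = [measured]
    runs = []
    for block in blocks:
        n = len(block)
        for i in range(n):
            for j in range(i + min_len, n + 1):
                seg = block[i:j]
                if not all(profile[f] >= threshold for f in seg):
                    continue
                left_ok = i == 0 or profile[block[i - 1]] < threshold
                right_ok = j == n or profile[block[j]] < threshold
                if left_ok and right_ok:
                    runs.append(tuple(seg))
    return sorted(runs, key=lambda r: order[r[0]])


class TestFindAffectedRuns:
    def test_minimal_run(self):
        profile = {500: 35, 1000: 40, 1500: 30, 2000: 10, 4000: 10, 6000: 10}
        runs = find_affected_runs(profile)
        assert [tuple(r) for r in runs] == [(500, 1000, 1500)]

    def test_below_min_len_is_empty(self):
        assert find_affected_runs({500: 35, 1000: 40, 2000: 5, 4000: 5, 6000: 5}) == []

    def test_two_disjoint_runs(self):
        profile = {250: 40, 500: 35, 1000: 30, 1500: 10, 2000: 5,
                   3000: 45, 4000: 40, 6000: 35, 8000: 50}
        runs = [tuple(r) for r in find_affected_runs(profile)]
        assert runs == [(250, 500, 1000), (3000, 4000, 6000, 8000)]
        assert runs == brute_force_runs(profile)

    def test_unmeasured_frequency_bridges_run_by_default(self):
        profile = {500: 40, 1000: 40, 2000: 40, 4000: 5, 6000: 5}  # 1500 skipped
        assert [tuple(r) for r in find_affected_runs(profile)] == [(500, 1000, 2000)]

    def test_strict_grid_mode_splits_at_unmeasured(self):
        profile = {500: 40, 1000: 40, 2000: 40, 4000: 5, 6000: 5}
        assert find_affected_runs(profile, strict_grid=True) == []

    @pytest.mark.parametrize("strict", [False, True])
    def test_matches_brute_force_on_random_profiles(self, strict):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            n_meas = rng.integers(1, 11)
            freqs = sorted(rng.choice(len(FREQUENCIES), size=n_meas, replace=False))
            profile = {FREQUENCIES[i]: float(5 * rng.integers(-4, 16)) for i in freqs}
            got = [tuple(r) for r in find_affected_runs(profile, strict_grid=strict)]
            assert got == brute_force_runs(profile, strict=strict)

    def test_empty_profile_rejected(self):
        with pytest.raises(AudiometryError):
            find_affected_runs({})


class TestAffectedFrequencySet:
    def test_union_of_runs(self):
        profile = {250: 40, 500: 35, 1000: 30, 1500: 10, 2000: 5,
                   3000: 45, 4000: 40, 6000: 35, 8000: 50}
        runs = find_affected_runs(profile)
        assert affected_frequency_set(runs) == (250, 500, 1000, 3000, 4000, 6000, 8000)

    def test_empty_runs_give_empty_set(self):
        assert affected_frequency_set([]) == ()

    def test_empty_set_rejected_by_ipta(self):
        with pytest.raises(NoAffectedRunError, match="criterion"):
            ipta(flat(50), ())


class TestClassifyDegree:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (40, DegreeClass.NO_MILD),
            (41, DegreeClass.MODERATE),
            (60, DegreeClass.MODERATE),
            (61, DegreeClass.SEVERE),
            (80, DegreeClass.SEVERE),
            (81, DegreeClass.PROFOUND),
            (80.0001, DegreeClass.PROFOUND),
        ],
    )
    def test_boundaries(self, value, expected):
        assert classify_degree(value) is expected

    def test_monotone(self):
        values = np.arange(-10, 121, 1.25)
        ranks = [classify_degree(v).rank for v in values]
        assert ranks == sorted(ranks)


class TestClassifyPattern:
    def test_low_frequency_and_range_specific(self):
        profile = {125: 40, 250: 40, 500: 40, 1000: 5, 2000: 5, 4000: 0, 6000: 0}
        p = classify_pattern(profile)
        assert p.low_frequency is True
        assert p.range_specific is True
        assert p.high_frequency is False

    def test_all_frequencies_affected(self):
        profile = {f: 50 for f in FREQUENCIES}
        p = classify_pattern(profile)
        assert p.low_frequency is True
        assert p.high_frequency is True
        assert p.range_specific is False

    def test_five_affected_is_not_range_specific(self):
        profile = {500: 5, 1000: 5, 2000: 40, 3000: 40, 4000: 40, 6000: 40, 8000: 40}
        p = classify_pattern(profile)
        assert p.range_specific is False
        assert p.high_frequency is True

    def test_low_frequency_indeterminate_without_125(self):
        profile = {250: 40, 500: 40, 1000: 40, 2000: 5, 4000: 5, 6000: 5}
        assert classify_pattern(profile).low_frequency is None

    def test_scattered_affected_not_range_specific(self):
        # one qualifying run plus an isolated affected frequency elsewhere
        profile = {250: 40, 500: 40, 1000: 40, 2000: 5, 4000: 5, 6000: 5, 8000: 45}
        assert classify_pattern(profile).range_specific is False


class TestScoreRecovery:
    def _triplet(self, initial, followup, contra=25):
        freqs = (500, 1000, 2000)
        mk = lambda lvl, side: ear(
            {**{f: lvl for f in freqs}, 4000: contra, 6000: contra}, side=side)
        return (mk(initial, "right"), mk(followup, "right"),
                ear({f: contra for f in FREQUENCIES if f in (500, 1000, 2000, 4000, 6000)},
                    side="left"))

    @pytest.mark.parametrize(
        "initial,followup,expected_rec,expected_cat",
        [
            (70, 30, 40, RecoveryCategory.FULL),      # back to within 10 dB of contra
            (70, 45, 25, RecoveryCategory.PARTIAL),   # >10 dB gain, criterion unmet
            (70, 60, 10, RecoveryCategory.NONE),      # <=10 dB gain
        ],
    )
    def test_guideline_taxonomy(self, initial, followup, expected_rec, expected_cat):
        res = score_recovery(*self._triplet(initial, followup), measure="ipta")
        assert res.frequencies == (500, 1000, 2000)
        assert res.recovery_db == pytest.approx(expected_rec)
        assert res.category is expected_cat

    def test_worsening_is_no_recovery(self):
        res = score_recovery(*self._triplet(70, 80), measure="ipta")
        assert res.recovery_db == pytest.approx(-10)
        assert res.category is RecoveryCategory.NONE

    def test_frequency_set_fixed_at_diagnosis(self):
        # follow-up loss pattern is irrelevant: the diagnostic set is reused
        initial, followup, contra = self._triplet(70, 30)
        res = score_recovery(initial, followup, contra, measure="ipta")
        assert res.frequencies == (500, 1000, 2000)
        assert res.contralateral_value == pytest.approx(25)

    def test_followup_missing_frequency_raises(self):
        initial, _, contra = self._triplet(70, 30)
        followup = ear({500: 30, 1000: 30, 4000: 25, 6000: 25})  # 2000 Hz not retested
        with pytest.raises(MissingFrequencyError, match="2000 Hz"):
            score_recovery(initial, followup, contra, measure="ipta")

    def test_no_qualifying_run_raises(self):
        aff = flat(30, side="right")
        contra = flat(10, side="left")
        with pytest.raises(NoAffectedRunError):
            score_recovery(aff, aff, contra, measure="ipta")

    def test_pta4_prefilled_full_at_diagnosis(self):
        # lesion at 125-500 Hz barely touches the PTA4 band
        aff = ear({125: 55, 250: 55, 500: 55, 1000: 15, 2000: 15, 4000: 15, 6000: 15},
                  side="right")
        contra = flat(15, side="left")
        res = score_recovery(aff, aff, contra, measure="pta4")
        assert res.prefilled_full_at_diagnosis
        assert res.category is RecoveryCategory.FULL

    def test_categories_partition_randomized(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            lesion = 5 * rng.integers(6, 15)
            follow_shift = 5 * rng.integers(-2, 14)
            initial, followup, contra = self._triplet(
                25 + lesion, max(-10, min(120, 25 + lesion - follow_shift)))
            res = score_recovery(initial, followup, contra, measure="ipta")
            full = res.followup_value - res.contralateral_value <= 10
            partial = (not full) and res.recovery_db > 10
            none = (not full) and res.recovery_db <= 10
            assert [full, partial, none].count(True) == 1
            assert res.category.value == ("full" if full else "partial" if partial else "none")
            if res.category is RecoveryCategory.FULL:
                assert res.recovery_db > 10  # interaural loss >= 30 forces this


class TestConductiveCheck:
    def test_large_air_bone_gap_flags_conductive(self):
        air = flat(60)
        bone = flat(25, freqs=(500, 1000, 2000, 4000), conduction="bone")
        assert conductive_check(air, bone) is True

    def test_small_gap_passes(self):
        air = flat(60)
        bone = flat(55, freqs=(500, 1000, 2000, 4000), conduction="bone")
        assert conductive_check(air, bone) is False

    def test_missing_bone_data_warns_and_passes(self):
        with pytest.warns(UserWarning, match="skipped"):
            assert conductive_check(flat(60), None) is False
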