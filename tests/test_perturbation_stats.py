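import numpy as np
import pandas as pd
import pytest

from glossperm.errors import ValidationError
from glossperm.perturbation_stats import (
    classify_shift_direction,
    per_level_samples,
    permutation_test,
    permutation_test_from_trials,
    repeated_injection_summary,
    shift_histogram_table,
    slope_timecourse,
)
from glossperm.synthetic_data import (
    BehaviorGroundTruth,
    simulate_muscimol_series,
    simulate_session_choices,
    trials_to_frame,
)


def _session_samples(truth, grid, seed):
    trials = trials_to_frame(simulate_session_choices(truth, grid, seed=seed))
    return (
        per_level_samples(trials, "stimulation", True),
        per_level_samples(trials, "stimulation", False),
    )


class TestPermutationTest:
    def test_identical_groups_zero_delta_nonsignificant(self, grid):
        truth = BehaviorGroundTruth(a_true=1.0, b_true=4.0)
        cond, _ = _session_samples(truth, grid, seed=3)
        copy = {k: v.copy() for k, v in cond.items()}
        res = permutation_test(cond, copy, n_perm=500, seed=0)
        assert res.delta_a == pytest.approx(0.0, abs=1e-10)
        assert res.delta_b == pytest.approx(0.0, abs=1e-10)
        assert not res.significant_a
        assert not res.significant_b

    def test_seeded_determinism(self, grid):
        truth = BehaviorGroundTruth(a_true=1.0, b_true=4.0, delta_b_stim=-1.0)
        cond, ctrl = _session_samples(truth, grid, seed=5)
        r1 = permutation_test(cond, ctrl, n_perm=300, seed=9)
        r2 = permutation_test(cond, ctrl, n_perm=300, seed=9)
        assert np.array_equal(r1.null_delta_b, r2.null_delta_b)
        assert r1.p_b == r2.p_b

    def test_unequal_group_sizes_raise(self):
        cond = {1: np.zeros(5), 2: np.ones(5), 3: np.ones(5)}
        ctrl = {1: np.zeros(4), 2: np.ones(5), 3: np.ones(5)}
        with pytest.raises(ValidationError):
            permutation_test(cond, ctrl, n_perm=10)

    def test_mismatched_levels_raise(self):
        cond = {1: np.zeros(5), 2: np.ones(5)}
        ctrl = {1: np.zeros(5), 3: np.ones(5)}
        with pytest.raises(ValidationError):
            permutation_test(cond, ctrl, n_perm=10)

    def test_null_length_accounts_for_drops(self, grid):
        truth = BehaviorGroundTruth(a_true=1.0, b_true=4.0)
        cond, ctrl = _session_samples(truth, grid, seed=1)
        res = permutation_test(cond, ctrl, n_perm=200, seed=4)
        assert len(res.null_delta_b) == res.n_perm - res.n_dropped

    def test_small_scale_type_one_calibration(self, grid):
        truth = BehaviorGroundTruth(a_true=1.0, b_true=4.0, delta_b_stim=0.0)
        rej = 0
        n_sessions = 40
        for i in range(n_sessions):
            cond, ctrl = _session_samples(truth, grid, seed=100 + i)
            res = permutation_test(cond, ctrl, n_perm=400, seed=i)
            rej += res.significant_b
        # expect ~5%; 3 MC SE of slack at this n
        assert rej / n_sessions <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_sessions)

    def test_strong_effect_detected(self, grid):
        truth = BehaviorGroundTruth(a_true=1.0, b_true=4.0, delta_b_stim=-1.5)
        hits = 0
        for i in range(25):
            cond, ctrl = _session_samples(truth, grid, seed=500 + i)
            res = permutation_test(cond, ctrl, n_perm=400, seed=i)
            hits += res.significant_b
        assert hits / 25 >= 0.7

    def test_independent_mode_runs(self, grid):
        truth = BehaviorGroundTruth(a_true=1.0, b_true=4.0)
        cond, ctrl = _session_samples(truth, grid, seed=2)
        res = permutation_test(cond, ctrl, n_perm=200, seed=3, mode="independent")
        assert res.mode == "independent"
        assert len(res.null_delta_b) > 0

    def test_unknown_mode_raises(self, grid):
        truth = BehaviorGroundTruth()
        cond, ctrl = _session_samples(truth, grid, seed=2)
        with pytest.raises(ValidationError):
            permutation_test(cond, ctrl, n_perm=10, mode="bogus")

    def test_null_pvalues_roughly_uniform(self, grid):
        # exchangeability: under the null the p-values should not pile up
        # near 0; check the empirical CDF at 0.25/0.5 within coarse bounds
        truth = BehaviorGroundTruth(a_true=1.0, b_true=4.0)
        ps = []
        for i in range(60):
            cond, ctrl = _session_samples(truth, grid, seed=900 + i)
            ps.append(permutation_test(cond, ctrl, n_perm=300, seed=i).p_b)
        ps = np.array(ps)
        assert abs((ps <= 0.5).mean() - 0.5) < 0.2
        assert (ps <= 0.1).mean() < 0.25


class TestShiftDirection:
    def test_negative_significant_shift_is_glossier(self, grid):
        # generator check: delta_b_stim < 0 raises P(glossier) under stim
        truth = BehaviorGroundTruth(a_true=1.5, b_true=4.0, delta_b_stim=-1.5)
        trials = trials_to_frame(simulate_session_choices(truth, grid, seed=11))
        res = permutation_test_from_trials(trials, n_perm=400, seed=0)
        assert res.delta_b < 0
        if res.significant_b:
            assert classify_shift_direction(res) == "glossier"

    def test_positive_significant_shift_is_less_glossy(self, grid):
        truth = BehaviorGroundTruth(a_true=1.5, b_true=4.0, delta_b_stim=+1.5)
        trials = trials_to_frame(simulate_session_choices(truth, grid, seed=12))
        res = permutation_test_from_trials(trials, n_perm=400, seed=0)
        assert res.delta_b > 0
        if res.significant_b:
            assert classify_shift_direction(res) == "less_glossy"

    def test_nonsignificant_is_none(self, grid):
        truth = BehaviorGroundTruth(a_true=1.0, b_true=4.0)
        cond, _ = _session_samples(truth, grid, seed=3)
        res = permutation_test(cond, {k: v.copy() for k, v in cond.items()},
                               n_perm=200, seed=0)
        assert classify_shift_direction(res) == "none"


class TestTimecourse:
    def _series(self, truth, grid_no_stim, seed0):
        recs = simulate_muscimol_series(
            truth, grid_no_stim, seeds=[seed0, seed0 + 1, seed0 + 2, seed0 + 3]
        )
        frame = trials_to_frame(recs)
        pre = frame[frame["epoch"] == "pre"]
        post = {
            float(t): chunk
            for t, chunk in frame[frame["epoch"] == "post"].groupby("timepoint_h")
        }
        return pre, post

    def test_missing_pre_session_raises(self, grid_no_stim):
        truth = BehaviorGroundTruth()
        _, post = self._series(truth, grid_no_stim, 0)
        with pytest.raises(ValidationError):
            slope_timecourse(pd.DataFrame(), post, n_perm=10, seed=0)

    def test_one_point_per_timepoint(self, grid_no_stim):
        truth = BehaviorGroundTruth(a_true=2.0)
        pre, post = self._series(truth, grid_no_stim, 10)
        points = slope_timecourse(pre, post, n_perm=200, seed=0)
        assert [p.timepoint_h for p in points] == [0.5, 18.0, 42.0]

    def test_expected_minimum_at_18h(self, grid_no_stim):
        # expectation over replicates: slope difference most negative at 18 h
        truth = BehaviorGroundTruth(a_true=2.0, b_true=4.0)
        sums = {0.5: 0.0, 18.0: 0.0, 42.0: 0.0}
        n_rep = 60
        for r in range(n_rep):
            pre, post = self._series(truth, grid_no_stim, 1000 + 10 * r)
            points = slope_timecourse(pre, post, n_perm=1, seed=r)
            for p in points:
                sums[p.timepoint_h] += p.slope_difference
        means = {t: s / n_rep for t, s in sums.items()}
        assert means[18.0] < means[0.5] < 0
        assert abs(means[42.0]) < 0.4  # multiplier 1 -> expected 0


class TestRepeatedInjection:
    def test_single_injection_trend_undefined(self):
        frame = repeated_injection_summary([(0, -1.2, True)])
        assert len(frame) == 1
        assert np.isnan(frame["trend_rho"].iloc[0])

    def test_attenuated_effects_decreasing_trend(self):
        frame = repeated_injection_summary(
            [(0, -1.2, True), (1, -0.6, False), (2, -0.3, False)]
        )
        assert frame["trend_rho"].iloc[0] == pytest.approx(-1.0)

    def test_empty_raises(self):
        with pytest.raises(ValidationError):
            repeated_injection_summary([])

    def test_generator_closed_form_attenuation(self, grid_no_stim):
        # attenuation 0.5: effective 18h multipliers 0.4, 0.7, 0.85 ->
        # expected |slope drop| strictly decreasing across injections
        from glossperm.synthetic_data import slope_multiplier

        truth = BehaviorGroundTruth(injection_attenuation=0.5)
        mults = [slope_multiplier(truth, 18.0, k) for k in range(3)]
        assert mults == pytest.approx([0.4, 0.7, 0.85])
        drops = [1 - m for m in mults]
        assert drops == sorted(drops, reverse=True)


class TestShiftHistogram:
    def test_counts_split_by_significance(self):
        table = shift_histogram_table([-0.8, -0.1, 0.3], [True, False, False],
                                      bin_width=0.5)
        assert table["n_significant"].sum() == 1
        assert table["n_nonsignificant"].sum() == 2

    def test_empty_input(self):
        table = shift_histogram_table([], [])
        assert table.empty
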