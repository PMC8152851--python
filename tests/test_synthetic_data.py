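import numpy as np
import pytest

from glossperm.errors import ValidationError
from glossperm.synthetic_data import (
    BehaviorGroundTruth,
    GroundTruthUnit,
    choice_probability,
    linear_tuning,
    make_unit,
    mean_response_rate,
    simulate_muscimol_series,
    simulate_session_choices,
    simulate_unit_responses,
    slope_multiplier,
    spikes_to_frame,
    trials_to_frame,
    ground_truth_manifest,
)


class TestGroundTruthValidation:
    def test_nonpositive_base_rate(self):
        with pytest.raises(ValidationError):
            GroundTruthUnit("u", {"s": 1.0}, base_rate=0.0)

    def test_non_monotone_tuning(self):
        with pytest.raises(ValidationError):
            GroundTruthUnit("u", {"s": 1.0}, tuning=(0.0, 0.5, 0.2))

    def test_negative_composed_rate(self):
        unit = GroundTruthUnit("u", {"s": -50.0}, base_rate=10.0)
        with pytest.raises(ValidationError):
            mean_response_rate(unit, "s", 7, shuffled=False)

    def test_behavior_slope_positive(self):
        with pytest.raises(ValidationError):
            BehaviorGroundTruth(a_true=0.0)

    def test_attenuation_range(self):
        with pytest.raises(ValidationError):
            BehaviorGroundTruth(injection_attenuation=0.0)


class TestSpikeSimulator:
    def test_determinism(self, selectivity_set):
        unit = make_unit("u0", ["s0007-c1"], kind="flat")
        unit = make_unit("u0", [s for s in selectivity_set.frame["shape_id"].unique()])
        a = simulate_unit_responses(unit, selectivity_set, n_repeats=5, seed=3)
        b = simulate_unit_responses(unit, selectivity_set, n_repeats=5, seed=3)
        assert spikes_to_frame(a).equals(spikes_to_frame(b))

    def test_minimum_repeats_enforced(self, selectivity_set, shape_ids):
        unit = make_unit("u0", shape_ids)
        with pytest.raises(ValidationError):
            simulate_unit_responses(unit, selectivity_set, n_repeats=4, seed=0)

    def test_flat_unit_response_matches_baseline(self, selectivity_set, shape_ids):
        unit = make_unit("u0", shape_ids, kind="flat", base_rate=40.0)
        recs = simulate_unit_responses(unit, selectivity_set, n_repeats=50, seed=5)
        frame = spikes_to_frame(recs)
        # both windows Poisson(40*0.3=12); means agree within sampling error
        assert frame["response_count"].mean() == pytest.approx(
            frame["baseline_count"].mean(), abs=0.5
        )

    def test_level7_mean_within_3se_of_poisson_oracle(self, selectivity_set, shape_ids):
        # base 10 spk/s, gain 40, linear tuning: level-7 mean rate 50 spk/s,
        # so counts ~ Poisson(15) over the 300-ms window
        unit = make_unit("u0", shape_ids, gain=40.0, base_rate=10.0)
        recs = simulate_unit_responses(unit, selectivity_set, n_repeats=100, seed=9)
        frame = spikes_to_frame(recs)
        top = frame[(frame["gloss_level"] == 7) & (~frame["shuffled"]) &
                    (frame["shape_id"] == shape_ids[0])]
        expected = 50.0 * 0.3
        se = np.sqrt(expected / len(top))
        assert abs(top["response_count"].mean() - expected) < 3 * se

    def test_poisson_dispersion_near_one(self, selectivity_set, shape_ids):
        unit = make_unit("u0", shape_ids, gain=30.0, base_rate=20.0)
        recs = simulate_unit_responses(unit, selectivity_set, n_repeats=200, seed=2)
        frame = spikes_to_frame(recs)
        sub = frame[(~frame["shuffled"]) & (frame["gloss_level"] == 4) &
                    (frame["shape_id"] == shape_ids[1])]
        counts = sub["response_count"].to_numpy()
        fano = counts.var(ddof=1) / counts.mean()
        assert 0.75 < fano < 1.25

    def test_shuffled_flat_without_confound(self, selectivity_set, shape_ids):
        unit = make_unit("u0", shape_ids, gain=40.0, base_rate=20.0)
        for level in (1, 7):
            assert mean_response_rate(unit, shape_ids[0], level, shuffled=True) == 20.0

    def test_shuffled_tracks_level_with_luminance_confound(self, shape_ids):
        unit = make_unit("u0", shape_ids, kind="luminance", gain=40.0, base_rate=20.0)
        r1 = mean_response_rate(unit, shape_ids[0], 1, shuffled=True)
        r7 = mean_response_rate(unit, shape_ids[0], 7, shuffled=True)
        assert r1 == 20.0
        assert r7 == 60.0

    def test_matte_unit_reversed_tuning(self, shape_ids):
        unit = make_unit("u0", shape_ids, gain=40.0, base_rate=10.0, sign=-1)
        assert mean_response_rate(unit, shape_ids[0], 1, False) == 50.0
        assert mean_response_rate(unit, shape_ids[0], 7, False) == 10.0


class TestChoiceGenerator:
    def test_midpoint_probability_half(self):
        truth = BehaviorGroundTruth(a_true=1.3, b_true=4.0)
        assert choice_probability(truth, 4.0) == pytest.approx(0.5)

    def test_step_function_limit(self):
        truth = BehaviorGroundTruth(a_true=80.0, b_true=4.0)
        assert choice_probability(truth, 5) >= 1 - 1e-12
        assert choice_probability(truth, 3) <= 1e-12

    def test_stim_offset_shift_raises_glossier_probability(self):
        truth = BehaviorGroundTruth(a_true=1.0, b_true=4.0, delta_b_stim=-1.0)
        assert choice_probability(truth, 4, stimulation=True) > choice_probability(
            truth, 4, stimulation=False
        )

    def test_one_trial_per_condition(self, grid):
        truth = BehaviorGroundTruth()
        trials = trials_to_frame(
            simulate_session_choices(truth, grid, seed=0, session_id="s")
        )
        assert len(trials) == 210
        key = ["gloss_level", "shape_id", "illumination_id", "stimulation"]
        assert not trials.duplicated(subset=key).any()

    def test_determinism(self, grid):
        truth = BehaviorGroundTruth()
        a = trials_to_frame(simulate_session_choices(truth, grid, seed=77))
        b = trials_to_frame(simulate_session_choices(truth, grid, seed=77))
        assert a.equals(b)

    def test_level4_choice_recorded_and_reward_random(self, grid):
        truth = BehaviorGroundTruth(a_true=50.0, b_true=4.0)
        frames = [
            trials_to_frame(simulate_session_choices(truth, grid, seed=s))
            for s in range(30)
        ]
        import pandas as pd

        trials = pd.concat(frames)
        mid = trials[trials["gloss_level"] == 4]
        assert mid["choice"].isin(["glossier", "less_glossy"]).all()
        # random reward at the reference level: close to 1/2
        assert abs(mid["rewarded"].mean() - 0.5) < 0.05

    def test_reward_tracks_correctness_off_reference(self, grid):
        truth = BehaviorGroundTruth(a_true=1.0, b_true=4.0)
        trials = trials_to_frame(simulate_session_choices(truth, grid, seed=5))
        off = trials[trials["gloss_level"] != 4]
        correct = (off["choice"] == "glossier") == (off["gloss_level"] > 4)
        assert (off["rewarded"] == correct).all()

    def test_empirical_choice_frequency_matches_logistic(self, grid):
        truth = BehaviorGroundTruth(a_true=1.0, b_true=4.0)
        import pandas as pd

        trials = pd.concat(
            trials_to_frame(simulate_session_choices(truth, grid, seed=s))
            for s in range(60)
        )
        ctrl = trials[~trials["stimulation"]]
        emp = (
            ctrl.assign(g=(ctrl["choice"] == "glossier").astype(float))
            .groupby("gloss_level")["g"]
            .mean()
        )
        for level, p_hat in emp.items():
            p = choice_probability(truth, level)
            n = 15 * 60
            se = np.sqrt(p * (1 - p) / n)
            assert abs(p_hat - p) < 4 * se


class TestMuscimol:
    def test_slope_multiplier_closed_form(self):
        truth = BehaviorGroundTruth(injection_attenuation=0.5)
        # second injection (0-based index 1) at 18 h: 1 - 0.6 * 0.5 = 0.7
        assert slope_multiplier(truth, 18.0, injection_index=1) == pytest.approx(0.7)
        assert slope_multiplier(truth, 18.0, injection_index=0) == pytest.approx(0.4)
        assert slope_multiplier(truth, None) == 1.0

    def test_missing_timepoint_raises(self):
        truth = BehaviorGroundTruth()
        with pytest.raises(ValidationError):
            slope_multiplier(truth, 99.0)

    def test_series_one_session_per_timepoint(self, grid_no_stim):
        truth = BehaviorGroundTruth()
        recs = simulate_muscimol_series(truth, grid_no_stim, seeds=[1, 2, 3, 4])
        frame = trials_to_frame(recs)
        assert len(frame) == 4 * 105
        assert set(frame["epoch"]) == {"pre", "post"}
        assert sorted(frame.loc[frame["epoch"] == "post", "timepoint_h"].unique()) == [
            0.5,
            18.0,
            42.0,
        ]

    def test_seed_count_mismatch_raises(self, grid_no_stim):
        with pytest.raises(ValidationError):
            simulate_muscimol_series(BehaviorGroundTruth(), grid_no_stim, seeds=[1, 2])

    def test_default_profile_minimum_at_18h(self):
        truth = BehaviorGroundTruth()
        mults = {tp: slope_multiplier(truth, tp) for tp in (0.5, 18.0, 42.0)}
        assert min(mults, key=mults.get) == 18.0
        assert mults[42.0] == 1.0

    def test_manifest_round_trips_through_json(self):
        import json

        truth = BehaviorGroundTruth(delta_b_stim=-1.5)
        payload = ground_truth_manifest(truth, seed=7)
        loaded = json.loads(json.dumps(payload))
        assert loaded["a_true"] == 1.0
        assert loaded["delta_b_stim"] == -1.5
        assert loaded["seed"] == 7
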