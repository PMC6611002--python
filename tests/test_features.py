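import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import steftr
from steftr.features import (
    FEATURE_ORDER,
    TimeParameters,
    auto_time_parameters,
    build_histograms,
    compute_primitives,
    feature_streams,
    sliding_stats,
    time_differential,
    wrap_degrees,
)


class TestAutoTimeParameters:
    def test_worm_preset(self):
        p = auto_time_parameters([600.0], 1.0, preset="worm")
        assert (p.time_unit, p.window) == (1.0, 12.0)

    def test_penguin_preset(self):
        p = auto_time_parameters([2279 * 60.0], 60.0, preset="penguin")
        assert (p.time_unit, p.window) == (60.0, 1200.0)

    def test_rule_of_thumb_snaps_and_floors(self):
        # median 600 s -> raw (0.6, 6) -> snapped (0.5, 5) -> unit floored at native 1 s
        p = auto_time_parameters([600.0], 1.0)
        assert p.time_unit == 1.0
        assert p.window == 5.0

    def test_empty_durations_rejected(self):
        with pytest.raises(ValueError):
            auto_time_parameters([], 1.0)

    def test_window_frames_odd(self):
        assert TimeParameters(1.0, 12.0).window_frames() == 13
        assert TimeParameters(1.0, 5.0).window_frames() == 5
        assert TimeParameters(1.0, None).window_frames() is None


class TestComputePrimitives:
    def test_three_four_five_step(self):
        tr = steftr.Trajectory("a", [0.0, 1.0], [[0, 0], [3, 4]])
        v, b = compute_primitives(tr, 1.0)
        assert v[0] == pytest.approx(5.0)

    def test_straight_north_bearing_zero(self):
        tr = steftr.Trajectory("a", [0, 1, 2], [[0, 0], [0, 1], [0, 2]])
        _, b = compute_primitives(tr, 1.0)
        assert np.allclose(b, 0.0)

    def test_stationary_frame_carries_bearing_forward(self):
        tr = steftr.Trajectory("a", [0, 1, 2], [[0, 0], [1, 0], [1, 0]])
        v, b = compute_primitives(tr, 1.0)
        assert v[1] == 0.0
        assert b[1] == pytest.approx(90.0)  # east, carried forward


class TestTimeDifferential:
    def test_wraps_across_north(self):
        assert time_differential([350.0, 10.0], circular=True)[0] == pytest.approx(20.0)

    def test_constant_series_zero(self):
        assert np.allclose(time_differential([2.0, 2.0, 2.0]), 0.0)

    def test_half_turn_maps_to_upper_boundary(self):
        assert time_differential([0.0, 180.0], circular=True)[0] == pytest.approx(180.0)

    @given(st.lists(st.floats(0, 360, exclude_max=True), min_size=2, max_size=30))
    def test_wrapped_difference_stays_in_half_open_interval(self, bearings):
        db = time_differential(bearings, circular=True)
        assert np.all(db > -180.0) and np.all(db <= 180.0)


class TestSlidingStats:
    def test_constant_series_has_zero_variance(self):
        _, var = sliding_stats(np.full(9, 3.0), 3)
        assert np.allclose(var[1:-1], 0.0)

    def test_center_mean_of_simple_window(self):
        ave, _ = sliding_stats(np.array([1.0, 2.0, 3.0]), 3)
        assert ave[1] == pytest.approx(2.0)
        assert np.isnan(ave[0]) and np.isnan(ave[2])

    def test_turn_burst_raises_variance_only_near_burst(self):
        # the canonical sudden-turn stream: flat, then large heading changes
        db = np.array([0, 0, 0, 0, 0, 0, 180, 0, 90, 0, 270], dtype=float)
        _, var = sliding_stats(db, 5)
        flat = var[2:4]  # windows fully inside the quiet prefix
        busy = var[6:9]
        assert np.allclose(flat, 0.0)
        assert np.all(busy > 1000)
        # exact values agree with a direct windowed computation
        for k in range(2, 9):
            assert var[k] == pytest.approx(np.var(db[k - 2 : k + 3]))

    def test_circular_mean_crosses_seam(self):
        ave, var = sliding_stats(np.array([358.0, 0.0, 2.0]), 3, circular=True)
        assert ave[1] == pytest.approx(0.0, abs=1e-9)
        assert var[1] == pytest.approx(np.mean([4.0, 0.0, 4.0]))

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError):
            sliding_stats(np.arange(3.0), 5)


class TestBuildHistograms:
    def test_eight_histograms_with_conserved_counts(self, small_cohort):
        params = TimeParameters(1.0, 5.0)
        hists = build_histograms(small_cohort, params)
        assert set(hists) == set(FEATURE_ORDER)
        for h in hists.values():
            assert h.counts.sum() == h.n

    def test_duplicating_a_trajectory_doubles_counts(self):
        ts = steftr.simulate_state_switching(steftr.run_pirouette_spec(n_animals=1, n_frames=200, seed=7))
        tr = ts.trajectories[0]
        params = TimeParameters(1.0, 5.0)
        h1 = build_histograms(ts, params)
        twice = steftr.TrajectorySet([tr, tr])
        h2 = {
            k: np.histogram(v.values, bins=h1[k].bin_edges)[0]
            for k, v in build_histograms(twice, params).items()
        }
        for k in FEATURE_ORDER:
            assert np.array_equal(h2[k], 2 * h1[k].counts)

    def test_constant_feature_flagged_unusable(self):
        t = np.arange(100.0)
        tr = steftr.Trajectory("a", t, np.column_stack([np.zeros_like(t), t]))
        hists = build_histograms(steftr.TrajectorySet([tr]), TimeParameters(1.0, 5.0))
        assert not hists["V_Ave"].usable


class TestGeometricInvariances:
    @pytest.fixture()
    def cohort_streams(self, small_cohort):
        params = TimeParameters(1.0, 5.0)
        return small_cohort, params

    @staticmethod
    def _rotate(tr, deg):
        rad = np.radians(deg)
        rot = np.array([[np.cos(rad), -np.sin(rad)], [np.sin(rad), np.cos(rad)]])
        return steftr.Trajectory(tr.animal_id, tr.t, tr.xy @ rot.T, condition=tr.condition)

    def test_rotation_leaves_all_but_bearing_unchanged(self, cohort_streams):
        ts, params = cohort_streams
        tr = ts.trajectories[0]
        base = feature_streams(tr, params)
        rot = feature_streams(self._rotate(tr, 73.0), params)
        for kind in ("V_Ave", "V_Var", "dV_Ave", "dV_Var", "dB_Ave", "dB_Var"):
            assert np.allclose(base[kind], rot[kind], atol=1e-8, equal_nan=True)
        v, b0 = compute_primitives(tr, params.time_unit)
        _, b1 = compute_primitives(self._rotate(tr, 73.0), params.time_unit)
        shift = wrap_degrees(b1 - b0)
        assert np.allclose(shift, shift[0], atol=1e-8)

    def test_translation_leaves_everything_unchanged(self, cohort_streams):
        ts, params = cohort_streams
        tr = ts.trajectories[0]
        moved = steftr.Trajectory(tr.animal_id, tr.t, tr.xy + np.array([12.3, -4.5]))
        base, shifted = feature_streams(tr, params), feature_streams(moved, params)
        for kind in FEATURE_ORDER:
            assert np.allclose(base[kind], shifted[kind], atol=1e-9, equal_nan=True)

    def test_time_reversal_preserves_speed_multiset(self, cohort_streams):
        ts, params = cohort_streams
        tr = ts.trajectories[0]
        rev = steftr.Trajectory(tr.animal_id, tr.t, tr.xy[::-1])
        v_fwd, _ = compute_primitives(tr, params.time_unit)
        v_rev, _ = compute_primitives(rev, params.time_unit)
        assert np.allclose(np.sort(v_fwd), np.sort(v_rev))
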