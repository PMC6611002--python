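import numpy as np
import pytest

import steftr
from steftr.features import TimeParameters
from steftr.states import StateAnnotation
from steftr.worm import (
    LinearOdorField,
    WormFeatureConfig,
    classify_run_pirouette,
    detect_turns,
    directedness,
    fit_turn_interval_model,
    intersection_time,
    odor_exposure,
    weathervane,
    worm_feature_vector,
)


def _path_from_bearings(bearings, step=1.0):
    """Build a unit-step path whose successive step headings are given."""
    rad = np.radians(np.asarray(bearings, float))
    steps = step * np.column_stack([np.sin(rad), np.cos(rad)])
    xy = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    t = np.arange(len(xy), dtype=float)
    return steftr.Trajectory("w", t, xy)


class TestDetectTurns:
    def test_91_degree_change_is_a_turn(self):
        tr = _path_from_bearings([0.0, 91.0])
        assert detect_turns(tr)[1]

    def test_89_degree_change_is_not(self):
        tr = _path_from_bearings([0.0, 89.0])
        assert not detect_turns(tr).any()

    def test_straight_path_has_no_turns(self):
        tr = _path_from_bearings([45.0] * 10)
        assert not detect_turns(tr).any()


class TestTurnIntervalModel:
    def test_intersection_closed_form(self):
        assert intersection_time(1.0, 1.0, 0.1, 10.0) == pytest.approx(
            np.log(10) / 0.9, abs=1e-12
        )

    def test_equal_amplitudes_intersect_at_zero(self):
        assert intersection_time(1.0, 1.0, 1.0, 10.0) == pytest.approx(0.0)

    def test_recovers_two_exponential_mixture(self, rng):
        intervals = np.concatenate(
            [rng.exponential(2.0, 1000), rng.exponential(20.0, 1000)]
        )
        model = fit_turn_interval_model(intervals, seed=1)
        analytic = np.log((0.5 / 2) / (0.5 / 20)) / (1 / 2 - 1 / 20)
        assert model.crossing
        assert model.tau1 == pytest.approx(2.0, rel=0.25)
        assert model.tau2 == pytest.approx(20.0, rel=0.25)
        assert model.t_crit == pytest.approx(analytic, rel=0.25)

    def test_scale_equivariance(self, rng):
        intervals = np.concatenate(
            [rng.exponential(2.0, 1000), rng.exponential(20.0, 1000)]
        )
        t1 = fit_turn_interval_model(intervals, seed=1).t_crit
        t3 = fit_turn_interval_model(3.0 * intervals, seed=1).t_crit
        assert t3 == pytest.approx(3.0 * t1, rel=0.05)

    def test_too_few_intervals_rejected(self):
        with pytest.raises(ValueError):
            fit_turn_interval_model(np.ones(10))


class TestClassifyRunPirouette:
    @staticmethod
    def _with_turns(n, turn_frames):
        # a >90-degree heading change at step k puts the turn at frame k
        bearings = np.zeros(n - 1)
        heading = 0.0
        for k in range(n - 1):
            if k in turn_frames:
                heading += 120.0
            bearings[k] = heading
        return _path_from_bearings(bearings)

    def test_hand_worked_interval_rule(self):
        tr = self._with_turns(50, {10, 12, 14, 40})
        labels = classify_run_pirouette(tr, t_crit=6.0)
        assert np.all(labels[10:15] == 1)  # short intervals + bounding turns
        assert np.all(labels[15:40] == 0)  # 26 s interval is a run
        assert np.all(labels[:10] == 0)

    def test_no_turns_is_single_run(self):
        tr = _path_from_bearings([10.0] * 30)
        assert not classify_run_pirouette(tr, 6.0).any()

    def test_turn_every_second_is_all_pirouette(self):
        tr = self._with_turns(20, set(range(1, 19)))
        labels = classify_run_pirouette(tr, 6.0)
        assert np.all(labels[1:19] == 1)


class TestSegmentGeometry:
    def test_straight_segment_fully_directed(self):
        xy = np.column_stack([np.arange(10.0), np.zeros(10)])
        assert directedness(xy) == pytest.approx(1.0)

    def test_closed_loop_has_zero_directedness(self):
        theta = np.linspace(0, 2 * np.pi, 40)
        xy = np.column_stack([np.cos(theta), np.sin(theta)])
        xy[-1] = xy[0]
        assert directedness(xy) == pytest.approx(0.0, abs=1e-12)

    def test_right_angle_path(self):
        xy = np.array([[0, 0], [1, 0], [1, 1]], dtype=float)
        assert directedness(xy) == pytest.approx(np.sqrt(2) / 2)

    def test_invariant_under_rotation_and_translation(self, rng):
        xy = rng.normal(0, 1, (20, 2)).cumsum(axis=0)
        rad = np.radians(37.0)
        rot = np.array([[np.cos(rad), -np.sin(rad)], [np.sin(rad), np.cos(rad)]])
        assert directedness(xy @ rot.T + 5.0) == pytest.approx(directedness(xy))


class TestWeathervane:
    def test_straight_segment_zero(self):
        xy = np.column_stack([np.arange(10.0), np.zeros(10)])
        assert weathervane(xy, LinearOdorField((0.0, 1.0))) == pytest.approx(0.0, abs=1e-9)

    def test_arc_magnitude_equals_curvature(self):
        # quarter circle of radius R curving toward +x; gradient +x keeps the
        # up-gradient side fixed, so |WV| = (180/pi)/R deg per unit length
        R = 5.0
        theta = np.linspace(np.pi, np.pi / 2, 40)
        xy = np.column_stack([R + R * np.cos(theta), R * np.sin(theta)])
        wv = weathervane(xy, LinearOdorField((1.0, 0.0)))
        assert wv == pytest.approx(np.degrees(1.0 / R), rel=1e-3)
        assert wv > 0  # curving toward the up-gradient direction

    def test_mirror_reflection_symmetries(self):
        R = 5.0
        theta = np.linspace(np.pi, np.pi / 2, 40)
        xy = np.column_stack([R + R * np.cos(theta), R * np.sin(theta)])
        field = LinearOdorField((1.0, 0.0))
        # reflecting across the gradient axis preserves toward/away geometry
        along = xy * np.array([1.0, -1.0])
        assert weathervane(along, field) == pytest.approx(weathervane(xy, field), rel=1e-6)
        # reflecting across the perpendicular axis turns toward-gradient
        # curving into away-from-gradient curving: the sign flips
        across = xy * np.array([-1.0, 1.0])
        assert weathervane(across, field) == pytest.approx(-weathervane(xy, field), rel=1e-6)


class TestOdorExposure:
    def test_uniform_field_has_zero_change(self):
        xy = np.column_stack([np.arange(5.0), np.zeros(5)])
        c, dc = odor_exposure(xy, LinearOdorField((0.0, 0.0), base=3.0))
        assert np.allclose(c, 3.0)
        assert np.allclose(dc, 0.0)

    def test_unit_steps_up_a_linear_field(self):
        xy = np.column_stack([np.arange(5.0), np.zeros(5)])
        _, dc = odor_exposure(xy, LinearOdorField((1.0, 0.0)))
        assert np.allclose(dc, 1.0)

    def test_stationary_animal_in_time_varying_field(self):
        class Clock:
            def concentration(self, xy, t):
                return np.broadcast_to(np.atleast_1d(np.asarray(t, float)), (len(np.atleast_2d(xy)),)).copy()

            def gradient(self, xy, t):
                return np.zeros_like(np.atleast_2d(xy))

        xy = np.zeros((4, 2))
        c, dc = odor_exposure(xy, Clock(), t=np.arange(4.0))
        assert np.allclose(c, [0, 1, 2, 3])
        assert np.allclose(dc, 1.0)


class TestWormFeatureVector:
    @staticmethod
    def _annotation(labels_list, trajs):
        return StateAnnotation(
            labels=[np.asarray(l) for l in labels_list],
            feature_kind="dB_Var",
            model=None,
            params=TimeParameters(1.0, 5.0),
            trajset=steftr.TrajectorySet(trajs),
        )

    def test_column_count_matches_enumeration_scheme(self):
        assert len(WormFeatureConfig().column_names()) == 333

    def test_full_table_has_333_feature_columns(self, small_cohort):
        ann = steftr.estimate_states(small_cohort, steftr.EstimateConfig(seed=4))
        table = worm_feature_vector(ann, odor_field=LinearOdorField())
        feature_cols = [c for c in table.columns if c not in ("animal_id", "condition")]
        assert len(feature_cols) == 333

    def test_straight_constant_speed_segment(self):
        n = 40
        t = np.arange(n, dtype=float)
        xy = np.column_stack([np.zeros(n), 2.0 * t])
        tr = steftr.Trajectory("w", t, xy)
        ann = self._annotation([np.zeros(n, dtype=int)], [tr])
        table = worm_feature_vector(ann, odor_field=LinearOdorField((1.0, 0.0)))
        row = table.iloc[0]
        for period in ("Ini", "Mid", "Ter", "All"):
            assert row[f"V_Ave_{period}_w2"] == pytest.approx(2.0)
        assert row["Dir_All_w1"] == pytest.approx(1.0)
        assert row["Clst0Dur"] == pytest.approx(n)

    def test_short_segment_has_missing_long_window_cells(self):
        n = 4
        t = np.arange(n, dtype=float)
        tr = steftr.Trajectory("w", t, np.column_stack([t, np.zeros(n)]))
        ann = self._annotation([np.zeros(n, dtype=int)], [tr])
        row = worm_feature_vector(ann, odor_field=LinearOdorField()).iloc[0]
        assert np.isnan(row["V_Ave_Ini_w6"])

    def test_following_bout_duration_recorded(self):
        n = 30
        t = np.arange(n, dtype=float)
        tr = steftr.Trajectory("w", t, np.column_stack([t, np.zeros(n)]))
        labels = np.zeros(n, dtype=int)
        labels[12:20] = 1
        ann = self._annotation([labels], [tr])
        table = worm_feature_vector(ann, odor_field=LinearOdorField())
        assert table.iloc[0]["Clst0Dur"] == pytest.approx(12.0)
        assert table.iloc[0]["Clst1Dur"] == pytest.approx(8.0)


class TestPipelineAgreement:
    def test_threshold_classifier_agrees_with_cluster_pipeline(self, runpir_trajset):
        """Run/pirouette by turn-interval threshold vs by mixture clustering.

        The clustering side uses the worm-analysis configuration (cluster-0
        boundary extension enabled), whose whole purpose is to restore run
        boundaries to where a turn-based classifier places them.
        """
        pooled_threshold = []
        intervals = np.concatenate([steftr.turn_intervals(tr) for tr in runpir_trajset])
        model = fit_turn_interval_model(intervals, seed=1)
        t_crit = model.t_crit if model.crossing else 6.0
        for tr in runpir_trajset:
            pooled_threshold.append(classify_run_pirouette(tr, t_crit))
        threshold_labels = np.concatenate(pooled_threshold)
        annotation = steftr.estimate_states(
            runpir_trajset, steftr.EstimateConfig(seed=1, extend="auto")
        )
        cluster_labels = annotation.pooled_labels()
        mapping = steftr.align_clusters_to_states(cluster_labels, threshold_labels)
        grouped = np.array([mapping[int(c)] for c in cluster_labels])
        agreement = np.mean(grouped == threshold_labels)
        assert agreement >= 0.9
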