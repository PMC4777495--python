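import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stickmotion as sm
from conftest import make_series, random_trace
from oracles import bruteforce_segments


def as_tuples(seg: sm.SegmentationResult):
    return [(s.ref_frame, s.max_frame, s.max_distance, s.trailing) for s in seg.segments]


class TestSegmentMaxima:
    def test_sawtooth_hand_trace(self, sawtooth_trace):
        seg = sm.segment_maxima(sawtooth_trace, 0.0)
        assert as_tuples(seg) == [
            (0, 3, 3.0, False),
            (3, 5, 2.0, False),
            (5, 6, 1.0, True),
        ]

    def test_monotone_trace_yields_one_trailing_segment(self):
        trace = sm.MotionTrace("m", np.column_stack(([0, 1, 2, 3], np.zeros(4))))
        seg = sm.segment_maxima(trace)
        assert as_tuples(seg) == [(0, 3, 3.0, True)]
        assert sm.turning_angles(seg, trace) == []

    def test_constant_trace_has_no_segments(self):
        seg = sm.segment_maxima(sm.MotionTrace("c", np.ones((5, 2))))
        assert seg.n_maxima == 0
        assert sm.average_velocity(seg) is None

    def test_plateau_resolves_to_last_tied_frame(self):
        # distances 1, 1, 0: the tie extends the scan, so the maximum is at
        # frame 2, not frame 1
        trace = sm.MotionTrace("p", np.column_stack(([0, 1, 1, 0], np.zeros(4))))
        seg = sm.segment_maxima(trace)
        assert seg.segments[0].max_frame == 2

    def test_epsilon_suppresses_small_excursions(self, sawtooth_trace):
        seg = sm.segment_maxima(sawtooth_trace, epsilon=1.5)
        # the final excursion only reaches distance 1 and is dropped
        assert [s.max_distance for s in seg.segments] == [3.0, 2.0]

    def test_short_trace_and_negative_epsilon_rejected(self):
        with pytest.raises(sm.DataValidationError):
            sm.segment_maxima(sm.MotionTrace("s", np.zeros((1, 2))))
        with pytest.raises(sm.ParameterError):
            sm.segment_maxima(sm.MotionTrace("s", np.zeros((3, 2))), epsilon=-1)

    @settings(deadline=None, derandomize=True, max_examples=120)
    @given(seed=st.integers(0, 2**31 - 1), eps=st.sampled_from([0.0, 0.5, 2.0]))
    def test_matches_bruteforce_oracle(self, seed, eps):
        trace = random_trace(np.random.default_rng(seed), max_len=80)
        seg = sm.segment_maxima(trace, eps)
        assert as_tuples(seg) == bruteforce_segments(trace.points, eps)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_segments_chain_and_frames_increase(self, seed):
        trace = random_trace(np.random.default_rng(seed), max_len=120)
        seg = sm.segment_maxima(trace)
        for prev, cur in zip(seg.segments, seg.segments[1:]):
            assert cur.ref_frame == prev.max_frame
            assert cur.max_frame > prev.max_frame
        assert all(not s.trailing for s in seg.segments[:-1])


class TestVelocities:
    def test_segment_velocity_is_distance_over_elapsed(self):
        assert sm.segment_velocity(sm.MotionSegment(0, 3, 3.0)) == 1.0
        assert sm.segment_velocity(sm.MotionSegment(2, 6, 2.0)) == 0.5

    def test_sawtooth_average_velocity(self, sawtooth_trace):
        seg = sm.segment_maxima(sawtooth_trace)
        assert sm.average_velocity(seg) == 1.0

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(seed=st.integers(0, 2**31 - 1), scale=st.sampled_from([0.5, 10.0]))
    def test_scale_equivariance(self, seed, scale):
        trace = random_trace(np.random.default_rng(seed), max_len=60)
        seg = sm.segment_maxima(trace)
        scaled = sm.segment_maxima(sm.MotionTrace("x", trace.points * scale))
        assert scaled.n_maxima == seg.n_maxima
        v = sm.average_velocity(seg)
        sv = sm.average_velocity(scaled)
        if v is not None:
            assert sv == pytest.approx(scale * v, rel=1e-12)


class TestTurningAngles:
    def test_right_angle_and_reversal(self):
        # reference points (0,0), (1,0), (1,1): direction vectors (1,0), (0,1)
        l_trace = sm.MotionTrace(
            "L", np.array([[0, 0], [1, 0], [0.5, 0], [1, 1]], dtype=float)
        )
        seg = sm.segment_maxima(l_trace)
        assert sm.turning_angles(seg, l_trace) == [90.0]
        # reference points (0,0), (1,0), (0.5,0): vectors (1,0), (-0.5,0)
        back = sm.MotionTrace("back", np.array([[0, 0], [1, 0], [0.5, 0]], dtype=float))
        seg = sm.segment_maxima(back)
        assert sm.turning_angles(seg, back) == [180.0]

    def test_sawtooth_angles_are_reversals(self, sawtooth_trace):
        seg = sm.segment_maxima(sawtooth_trace)
        assert sm.turning_angles(seg, sawtooth_trace) == [180.0, 180.0]
        assert sm.average_turn_angle([180.0, 180.0]) == 180.0

    def test_average_of_empty_list_is_undefined(self):
        assert sm.average_turn_angle([]) is None

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(seed=st.integers(0, 2**31 - 1), angle=st.floats(0, 2 * math.pi))
    def test_rigid_motion_invariance(self, seed, angle):
        # generic (tie-free) trace: exact distance ties are not preserved
        # under floating-point rotation, so the invariance holds for paths
        # in general position
        rng = np.random.default_rng(seed)
        trace = sm.MotionTrace(
            "g", np.cumsum(rng.normal(0.0, 3.0, (int(rng.integers(2, 60)), 2)), axis=0)
        )
        c, s = math.cos(angle), math.sin(angle)
        rot = trace.points @ np.array([[c, -s], [s, c]]).T + np.array([17.0, -4.0])
        seg_a = sm.segment_maxima(trace)
        seg_b = sm.segment_maxima(sm.MotionTrace("r", rot))
        assert seg_a.n_maxima == seg_b.n_maxima
        assert [s.elapsed for s in seg_a.segments] == [s.elapsed for s in seg_b.segments]
        ang_a = sm.average_turn_angle(sm.turning_angles(seg_a, trace))
        ang_b = sm.average_turn_angle(sm.turning_angles(seg_b, sm.MotionTrace("r", rot)))
        if ang_a is not None:
            assert ang_b == pytest.approx(ang_a, abs=1e-6)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_angles_bounded(self, seed):
        trace = random_trace(np.random.default_rng(seed), max_len=100)
        seg = sm.segment_maxima(trace)
        for a in sm.turning_angles(seg, trace):
            assert 0.0 <= a <= 180.0


class TestBodypartAngles:
    def chain_series(self, right_pts, left_pts):
        names = {
            "throat": right_pts[0],
            "right_shoulder": right_pts[1],
            "right_elbow": right_pts[2],
            "right_hand": right_pts[3],
            "left_shoulder": left_pts[1],
            "left_elbow": left_pts[2],
            "left_hand": left_pts[3],
        }
        return make_series({k: np.asarray(v, dtype=float) for k, v in names.items()})

    def test_fully_extended_arms_give_zero(self):
        series = self.chain_series(
            right_pts=[(0, 0), (1, 0), (2, 0), (3, 0)],
            left_pts=[(0, 0), (-1, 0), (-2, 0), (-3, 0)],
        )
        assert sm.bodypart_angle_per_frame(series, sm.DEFAULT_TOPOLOGY, 0) == 0.0

    def test_single_right_angle_elbow(self):
        series = self.chain_series(
            right_pts=[(0, 0), (1, 0), (2, 0), (2, 1)],
            left_pts=[(0, 0), (-1, 0), (-2, 0), (-3, 0)],
        )
        assert sm.bodypart_angle_per_frame(series, sm.DEFAULT_TOPOLOGY, 0) == pytest.approx(90.0)

    def test_average_over_alternating_frames(self):
        bent = [(0, 0), (1, 0), (2, 0), (2, 1)]
        straight = [(0, 0), (1, 0), (2, 0), (3, 0)]
        left = [(0, 0), (-1, 0), (-2, 0), (-3, 0)]
        frames = []
        for pts in (straight, bent):
            frames.append(self.chain_series(pts, left))
        stacked = make_series(
            {
                name: np.vstack(
                    [f.trajectory(name) for f in frames]
                )
                for name in frames[0].landmarks
            }
        )
        assert sm.average_bodypart_angle(stacked) == pytest.approx(45.0)

    def test_translation_invariance(self):
        series = self.chain_series(
            right_pts=[(0, 0), (1, 0), (2, 1), (2, 3)],
            left_pts=[(0, 0), (-1, 0), (-2, -1), (-4, -1)],
        )
        shifted = make_series(
            {n: series.trajectory(n) + np.array([55.0, -9.0]) for n in series.landmarks}
        )
        assert sm.bodypart_angle_per_frame(shifted, sm.DEFAULT_TOPOLOGY, 0) == pytest.approx(
            sm.bodypart_angle_per_frame(series, sm.DEFAULT_TOPOLOGY, 0)
        )

    def test_missing_chain_landmark_is_a_data_error(self):
        series = self.chain_series(
            right_pts=[(0, 0), (1, 0), (2, 0), (3, 0)],
            left_pts=[(0, 0), (-1, 0), (-2, 0), (-3, 0)],
        )
        positions = series.positions.copy()
        positions[0, series.landmark_index("right_elbow")] = np.nan
        broken = sm.LandmarkSeries("b", series.frames, series.landmarks, positions)
        with pytest.raises(sm.DataValidationError, match="right_elbow"):
            sm.bodypart_angle_per_frame(broken, sm.DEFAULT_TOPOLOGY, 0)


class TestExtractFeatures:
    def test_constant_series_all_motion_measures_undefined(self):
        from conftest import full_figure_sawtooth

        fig = full_figure_sawtooth()
        frozen = make_series(
            {n: np.tile(fig.trajectory(n)[0], (4, 1)) for n in fig.landmarks}
        )
        feat = sm.extract_features(frozen)
        assert feat.n_maxima == 0
        assert feat.avg_velocity is None and feat.avg_turn_angle is None
        assert feat.avg_bodypart_angle is not None

    def test_sawtooth_as_single_landmark_aggregation(
        self, sawtooth_series, single_landmark_topology
    ):
        feat = sm.extract_features(sawtooth_series, single_landmark_topology)
        assert feat.n_maxima == 3
        assert feat.avg_velocity == 1.0
        assert feat.avg_turn_angle == 180.0
        assert feat.avg_bodypart_angle is None  # no chains in this topology

    def test_full_figure_sawtooth_matches_bare_trace(self):
        from conftest import full_figure_sawtooth

        feat = sm.extract_features(full_figure_sawtooth())
        assert feat.n_maxima == 3
        assert feat.avg_velocity == pytest.approx(1.0)
        assert feat.avg_turn_angle == pytest.approx(180.0)
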