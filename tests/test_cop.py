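import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_recording
from solecop.cop import (
    CoPTrajectory,
    SensorSubset,
    compute_cop,
    euclidean_rmse,
    p95_error,
    rmse,
)
from solecop.segment import StancePhase


def _traj(xs, ys, valid=None):
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    valid = np.ones(xs.shape, bool) if valid is None else np.asarray(valid, bool)
    T = xs.shape[0]
    return CoPTrajectory(
        cop_x=xs, cop_y=ys, valid=valid,
        substituted=np.zeros(T, bool),
        frame_indices=np.arange(T), segment_ids=np.zeros(T, int),
    )


def _single_phase_rec(pressures):
    """Recording of the given (T, 16) pressures plus one covering phase."""
    rec = make_recording(pressures)
    return rec, [StancePhase(0, rec.n_frames, rec.n_frames * 10.0)]


class TestSensorSubset:
    def test_mask_round_trip(self):
        s = SensorSubset((3, 1, 14))
        assert s.members == (1, 3, 14)
        assert SensorSubset.from_mask(s.mask) == s
        assert s.bitstring() == "1010000000000100"

    def test_rejects_empty_and_out_of_range(self):
        with pytest.raises(ValueError):
            SensorSubset(())
        with pytest.raises(ValueError):
            SensorSubset((0, 1))


class TestComputeCop:
    def test_single_loaded_sensor_gives_centroid(self, layout):
        arr = np.zeros((4, 16))
        arr[:, 4] = 3.0  # only sensor 5 loaded
        rec, phases = _single_phase_rec(arr)
        traj = compute_cop(rec, layout, SensorSubset.full(), phases)
        assert np.allclose(traj.cop_x, layout.sensor(5).centroid_x)
        assert np.allclose(traj.cop_y, layout.sensor(5).centroid_y)

    def test_equal_weights_give_midpoint(self, layout):
        arr = np.zeros((1, 16))
        # equalize P*A across sensors 1 and 14
        arr[0, 0] = 1.0 / layout.sensor(1).area
        arr[0, 13] = 1.0 / layout.sensor(14).area
        rec, phases = _single_phase_rec(arr)
        traj = compute_cop(rec, layout, (1, 14), phases)
        c1, c14 = layout.sensor(1), layout.sensor(14)
        assert traj.cop_x[0] == pytest.approx((c1.centroid_x + c14.centroid_x) / 2)
        assert traj.cop_y[0] == pytest.approx((c1.centroid_y + c14.centroid_y) / 2)

    def test_weighted_mean_1_2_1(self, layout):
        ids = (1, 5, 14)
        weights = {1: 1.0, 5: 2.0, 14: 1.0}
        arr = np.zeros((1, 16))
        for i in ids:
            arr[0, i - 1] = weights[i] / layout.sensor(i).area
        rec, phases = _single_phase_rec(arr)
        traj = compute_cop(rec, layout, ids, phases)
        xs = np.array([layout.sensor(i).centroid_x for i in ids])
        assert traj.cop_x[0] == pytest.approx(np.average(xs, weights=[1, 2, 1]))

    def test_scale_invariance(self, layout, sim_recording, sim_phases):
        a = compute_cop(sim_recording, layout, (1, 4, 14), sim_phases)
        scaled = sim_recording.copy()
        scaled.frames = scaled.frames * 3.0
        b = compute_cop(scaled, layout, (1, 4, 14), sim_phases)
        assert np.allclose(a.cop_x[a.valid], b.cop_x[b.valid])
        assert np.array_equal(a.valid, b.valid)

    def test_hold_last_fills_gap_and_marks_substituted(self, layout):
        arr = np.zeros((3, 16))
        arr[0, 0] = arr[2, 0] = 1.0  # sensor 1 silent on middle frame
        rec, phases = _single_phase_rec(arr)
        traj = compute_cop(rec, layout, (1,), phases, fallback="hold_last")
        assert traj.valid.all()
        assert traj.substituted.tolist() == [False, True, False]
        assert traj.cop_x[1] == traj.cop_x[0]

    def test_hold_does_not_cross_phase_boundaries(self, layout):
        arr = np.zeros((6, 16))
        arr[0, 0] = 1.0  # phase 0 frame 0 loaded; phase 1 never loaded
        rec = make_recording(arr)
        phases = [StancePhase(0, 3, 30.0), StancePhase(3, 6, 30.0)]
        traj = compute_cop(rec, layout, (1,), phases, fallback="hold_last")
        assert traj.valid.tolist() == [True, True, True, False, False, False]

    def test_exclude_policy_marks_invalid(self, layout):
        arr = np.zeros((3, 16))
        arr[0, 0] = arr[2, 0] = 1.0
        rec, phases = _single_phase_rec(arr)
        traj = compute_cop(rec, layout, (1,), phases, fallback="exclude")
        assert traj.valid.tolist() == [True, False, True]

    def test_full_set_is_exact_ground_truth(self, layout, sim_recording, sim_phases):
        gt = compute_cop(sim_recording, layout, SensorSubset.full(), sim_phases)
        again = compute_cop(sim_recording, layout, SensorSubset.full(), sim_phases)
        for axis in ("X", "Y", "XY"):
            assert rmse(gt, again, axis) == 0.0
            assert p95_error(gt, again, axis) == 0.0

    def test_no_valid_frame_raises(self, layout):
        arr = np.zeros((3, 16))
        arr[:, 1] = 1.0  # only sensor 2 loaded
        rec, phases = _single_phase_rec(arr)
        with pytest.raises(ValueError):
            compute_cop(rec, layout, (5,), phases)

    def test_convex_hull_containment(self, layout, sim_recording, sim_phases):
        from shapely.geometry import MultiPoint, Point

        ids = (1, 4, 14)
        traj = compute_cop(sim_recording, layout, ids, sim_phases)
        hull = MultiPoint(
            [tuple(layout.centroids()[i - 1]) for i in ids]
        ).convex_hull.buffer(1e-9)
        real = traj.valid & ~traj.substituted
        for x, y in zip(traj.cop_x[real], traj.cop_y[real]):
            assert hull.contains(Point(x, y))


class TestErrorMetrics:
    def test_identity_gives_zero(self):
        t = _traj([1, 2, 3], [4, 5, 6])
        assert rmse(t, t, "XY") == 0.0
        assert p95_error(t, t, "XY") == 0.0

    def test_constant_x_offset(self):
        gt = _traj([0, 0, 0], [0, 0, 0])
        est = _traj([4, 4, 4], [0, 0, 0])
        assert rmse(gt, est, "X") == pytest.approx(4.0)
        assert rmse(gt, est, "Y") == 0.0
        assert rmse(gt, est, "XY") == pytest.approx(4.0)

    @pytest.mark.parametrize("rx,ry,expected", [
        (7.60, 3.70, 8.45),   # 5-sensor XY-optimized configuration
        (14.37, 3.10, 14.70), # 5-sensor Y-optimized configuration
        (3.76, 2.65, 4.60),   # 7-sensor XY-optimized configuration
    ])
    def test_euclidean_combination_matches_printed_tables(self, rx, ry, expected):
        """The Euclidean-RMSE definition reproduces the global values
        implied by the per-axis values, to two decimals."""
        T = 10
        gt = _traj(np.zeros(T), np.zeros(T))
        est = _traj(np.full(T, rx), np.full(T, ry))
        assert rmse(gt, est, "XY") == pytest.approx(expected, abs=0.005)
        assert euclidean_rmse(rx, ry) == pytest.approx(expected, abs=0.005)

    def test_p95_linear_interpolation(self):
        errs = np.arange(1.0, 101.0)
        gt = _traj(np.zeros(100), np.zeros(100))
        est = _traj(errs, np.zeros(100))
        assert p95_error(gt, est, "X") == pytest.approx(95.05)

    def test_p95_single_frame(self):
        gt = _traj([0.0], [0.0])
        est = _traj([7.0], [0.0])
        assert p95_error(gt, est, "XY") == pytest.approx(7.0)

    def test_only_common_valid_frames_count(self):
        gt = _traj([0, 0, 0], [0, 0, 0])
        est = _traj([4, 100, 4], [0, 0, 0], valid=[True, False, True])
        assert rmse(gt, est, "X") == pytest.approx(4.0)

    def test_no_common_frames_raises(self):
        gt = _traj([0.0], [0.0], valid=[False])
        with pytest.raises(ValueError):
            rmse(gt, gt, "X")

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10_000), T=st.integers(1, 50))
    def test_pythagorean_identity(self, seed, T):
        """RMSE_XY^2 = RMSE_X^2 + RMSE_Y^2 on any shared frame set."""
        rng = np.random.default_rng(seed)
        gt = _traj(rng.normal(size=T), rng.normal(size=T))
        est = _traj(rng.normal(size=T), rng.normal(size=T))
        assert rmse(gt, est, "XY") ** 2 == pytest.approx(
            rmse(gt, est, "X") ** 2 + rmse(gt, est, "Y") ** 2, rel=1e-12
        )
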