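import numpy as np
import pandas as pd
import pytest

from solecop.cop import CoPTrajectory, SensorSubset
from solecop.report import (
    cross_performance,
    marginal_gains,
    selection_frequency,
    spatial_error_map,
)
from solecop.search import (
    OptimizationCurve,
    SubsetEvaluation,
    best_per_k,
    evaluate_subsets,
)
from test_search import toy_pool


def _curve(values, target="XY", members=None):
    """OptimizationCurve with the given best-metric sequence for k=1..len."""
    best = {}
    for k, v in enumerate(values, start=1):
        ids = members[k] if members else tuple(range(1, k + 1))
        m = {"rmse_x": v, "rmse_y": v, "rmse_xy": v}
        best[k] = SubsetEvaluation(
            subset=SensorSubset(ids), k=k, p95_x=v, p95_y=v, p95_xy=v,
            coverage=1.0, **m,
        )
    return OptimizationCurve(target=target, best=best)


def _traj(xs, ys):
    xs, ys = np.asarray(xs, float), np.asarray(ys, float)
    T = xs.shape[0]
    return CoPTrajectory(xs, ys, np.ones(T, bool), np.zeros(T, bool),
                         np.arange(T), np.zeros(T, int))


class TestMarginalGains:
    def test_hand_computed_sequence(self):
        mg = marginal_gains(_curve([20, 12, 8, 6.5, 5.8, 5.5]))
        assert mg.gains == pytest.approx({2: 8, 3: 4, 4: 1.5, 5: 0.7, 6: 0.3})
        # first sub-threshold gain is 0.7 at k=5, so 4 sensors suffice
        assert mg.inflection_k == 4

    def test_constant_sequence_inflects_immediately(self):
        mg = marginal_gains(_curve([5.0] * 6))
        assert all(g == 0 for g in mg.gains.values())
        assert mg.inflection_k == 1

    def test_no_inflection_when_gains_stay_large(self):
        mg = marginal_gains(_curve([100, 90, 80, 70, 60]))
        assert mg.inflection_k is None

    def test_gains_telescope_to_curve_span(self):
        vals = [20, 12, 8, 6.5, 5.8, 5.5, 5.0]
        mg = marginal_gains(_curve(vals))
        assert sum(mg.gains.values()) == pytest.approx(vals[0] - vals[-1])

    def test_incomplete_curve_rejected(self):
        curve = _curve([5, 4, 3])
        del curve.best[2]
        with pytest.raises(ValueError):
            marginal_gains(curve)


class TestSelectionFrequency:
    def test_counts_match_manual_tally(self):
        members = {k: tuple(range(1, k + 1)) for k in range(1, 7)}
        curves = {"XY": _curve([6, 5, 4, 3, 2, 1], members=members)}
        freq = selection_frequency(curves, (2, 5))
        # sensor 1 appears in the optimum at every k in 2..5, sensor 5 only at k=5
        assert freq.loc[1, "XY"] == 4
        assert freq.loc[5, "XY"] == 1
        assert freq.loc[6, "XY"] == 0

    def test_counts_bounded_by_k_range(self):
        pool, *_ = toy_pool(seed=2)
        evals = evaluate_subsets(pool, k_range=(1, 6))
        curves = {t: best_per_k(evals, t) for t in ("X", "Y", "XY")}
        freq = selection_frequency(curves, (2, 5))
        assert freq.to_numpy().max() <= 4
        assert freq.to_numpy().min() >= 0


@pytest.fixture(scope="module")
def evals():
    pool, *_ = toy_pool(seed=4)
    return evaluate_subsets(pool, k_range=(1, 6))


class TestCrossPerformance:

    def test_diagonal_dominance(self, evals):
        """Each target's own row attains the column minimum by definition
        of the argmin."""
        for k in (2, 3, 4):
            tab = cross_performance(evals, k)
            assert tab.loc["X", "rmse_x"] == tab["rmse_x"].min()
            assert tab.loc["Y", "rmse_y"] == tab["rmse_y"].min()
            assert tab.loc["XY", "rmse_xy"] == tab["rmse_xy"].min()

    def test_rows_satisfy_pythagorean_identity(self, evals):
        tab = cross_performance(evals, 3)
        for _, r in tab.iterrows():
            assert r.rmse_xy == pytest.approx(np.hypot(r.rmse_x, r.rmse_y), rel=1e-9)

    def test_coincident_x_and_xy_rows_when_x_dominates(self):
        """When X error dwarfs Y error, the X- and XY-optimal subsets agree."""
        rows = []
        for mask, rx, ry in ((0b011, 30.0, 0.10), (0b101, 10.0, 0.30),
                             (0b110, 20.0, 0.05)):
            rows.append({"mask": mask, "k": 2, "rmse_x": rx, "rmse_y": ry,
                         "rmse_xy": float(np.hypot(rx, ry)), "p95_x": 0.0,
                         "p95_y": 0.0, "p95_xy": 0.0, "coverage": 1.0})
        tab = cross_performance(pd.DataFrame(rows), 2)
        assert tab.loc["X", "sensors"] == tab.loc["XY", "sensors"]
        assert tab.loc["Y", "sensors"] != tab.loc["X", "sensors"]


class TestSpatialErrorMap:
    def test_zero_error_in_occupied_cells(self, layout):
        t = _traj([50, 100, 150], [30, 40, 50])
        emap = spatial_error_map(t, t, layout)
        occ = emap.counts > 0
        assert occ.sum() == 3
        assert np.all(emap.values[occ] == 0.0)
        assert np.isnan(emap.values[~occ]).all()

    def test_single_frame_error_lands_in_one_cell(self, layout):
        gt = _traj([100.0], [45.0])
        est = _traj([105.0], [45.0])
        emap = spatial_error_map(gt, est, layout, axis="XY")
        assert emap.counts.sum() == 1
        assert emap.values[emap.counts > 0][0] == pytest.approx(5.0)

    def test_weighted_cell_mean_recovers_overall_mean(self, layout):
        rng = np.random.default_rng(0)
        T = 400
        gx = rng.uniform(10, 260, T)
        gy = rng.uniform(5, 85, T)
        ex, ey = gx + rng.normal(0, 3, T), gy + rng.normal(0, 3, T)
        emap = spatial_error_map(_traj(gx, gy), _traj(ex, ey), layout, axis="XY")
        occ = emap.counts > 0
        pooled = np.sum(emap.values[occ] * emap.counts[occ]) / emap.counts.sum()
        assert pooled == pytest.approx(np.mean(np.hypot(gx - ex, gy - ey)), rel=1e-9)

    def test_errors_confined_to_anterior_third(self, layout):
        gx = np.linspace(10, 260, 100)
        gy = np.full(100, 45.0)
        ex = gx + np.where(gx > 2 * layout.length / 3, 8.0, 0.0)
        emap = spatial_error_map(_traj(gx, gy), _traj(ex, gy), layout, axis="X")
        centers = 0.5 * (emap.x_edges[:-1] + emap.x_edges[1:])
        elevated = np.nan_to_num(emap.values) > 1.0
        assert elevated.any()
        assert np.all(centers[elevated.any(axis=1)] > 2 * layout.length / 3 - 10)

    def test_clip_value_is_99th_percentile(self, layout):
        T = 200
        gx = np.linspace(20, 250, T)
        gy = np.full(T, 45.0)
        errs = np.linspace(0, 10, T)
        emap = spatial_error_map(_traj(gx, gy), _traj(gx + errs, gy), layout, axis="X")
        assert emap.clip_value == pytest.approx(np.percentile(errs, 99))
        assert emap.clipped()[emap.counts > 0].max() <= emap.clip_value + 1e-12
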