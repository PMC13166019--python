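"""Summary analyses over the optimization results.

* Marginal-gain analysis: the RMSE reduction obtained by allowing one more
  sensor, and the inflection point — the smallest sensor count beyond which
  the next gain falls below a threshold (1.5 mm by default), i.e. the
  "sufficient" sensor count.
* Selection frequency: how often each sensor appears in the optimal subsets
  across sizes k = 2..15, per optimization target.
* Cross-performance: the 3x3 table crossing the layouts optimal for X, Y and
  XY at a fixed k with the three error metrics, exposing directional
  trade-offs.
* Spatial error maps: mean absolute error binned on a regular grid over the
  insole by ground-truth CoP location, clipped for display at the 99th
  percentile of the error distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binned_statistic_2d

from .cop import AXES, CoPTrajectory
from .geometry import N_SENSORS, InsoleLayout
from .search import OptimizationCurve, SubsetEvaluation, best_per_k, metric_column


@dataclass
class MarginalGainSeries:
    """Per-k accuracy gain for one target; ``gains[k]`` is the RMSE drop (mm)
    from k-1 to k sensors. ``inflection_k`` is the last k before the first
    sub-threshold gain (None when every gain stays above the threshold)."""

    target: str
    gains: dict[int, float]
    threshold: float
    inflection_k: int | None


def marginal_gains(
    curve: OptimizationCurve, threshold: float = 1.5
) -> MarginalGainSeries:
    """Differences of the best-metric curve and the threshold inflection.

    ``inflection_k`` is the smallest k whose next addition gains less than
    ``threshold`` mm — equivalently the k preceding the first sub-threshold
    gain.
    """
    ks = sorted(curve.best)
    if len(ks) < 2 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("optimization curve must cover a contiguous k range")
    gains = {k: curve.metric(k - 1) - curve.metric(k) for k in ks[1:]}
    inflection = None
    for k in ks[1:]:
        if gains[k] < threshold:
            inflection = k - 1
            break
    return MarginalGainSeries(
        target=curve.target, gains=gains, threshold=threshold, inflection_k=inflection
    )


def selection_frequency(
    curves: Mapping[str, OptimizationCurve], k_range: tuple[int, int] = (2, 15)
) -> pd.DataFrame:
    """Count, per sensor and target, the subset sizes k in ``k_range`` whose
    optimal subset contains the sensor. Rows: sensor ids 1..16."""
    k_lo, k_hi = k_range
    data = {}
    for target, curve in curves.items():
        counts = np.zeros(N_SENSORS, dtype=int)
        for k in range(k_lo, k_hi + 1):
            for sid in curve.best[k].subset.members:
                counts[sid - 1] += 1
        data[target] = counts
    return pd.DataFrame(data, index=pd.RangeIndex(1, N_SENSORS + 1, name="sensor"))


def cross_performance(evaluations: pd.DataFrame, k: int) -> pd.DataFrame:
    """3x3 cross-performance table at subset size ``k``: rows are the layouts
    optimal for targets X, Y and XY; columns their RMSE_X/Y/XY (mm)."""
    rows = []
    for target in ("X", "Y", "XY"):
        ev: SubsetEvaluation = best_per_k(evaluations, target).best[k]
        rows.append(
            {
                "target": target,
                "sensors": ", ".join(str(i) for i in ev.subset.members),
                "rmse_x": ev.rmse_x,
                "rmse_y": ev.rmse_y,
                "rmse_xy": ev.rmse_xy,
            }
        )
    return pd.DataFrame(rows).set_index("target")


@dataclass
class ErrorMap:
    """Binned mean absolute error (mm) over the insole bounding box.

    ``values`` is (nx, ny) with NaN marking cells never visited by the
    ground-truth CoP (distinct from true zero error); ``clip_value`` is the
    99th percentile of the per-frame error distribution, the recommended
    display ceiling.
    """

    values: np.ndarray  # (nx, ny), mm
    counts: np.ndarray  # (nx, ny), frames per cell
    x_edges: np.ndarray  # (nx + 1,), mm
    y_edges: np.ndarray  # (ny + 1,), mm
    clip_value: float
    axis: str

    def clipped(self) -> np.ndarray:
        return np.minimum(self.values, self.clip_value)


def spatial_error_map(
    gt: CoPTrajectory,
    est: CoPTrajectory,
    layout: InsoleLayout,
    grid: tuple[int, int] = (40, 20),
    axis: str = "XY",
) -> ErrorMap:
    """Bin the per-frame error by ground-truth CoP cell; see :class:`ErrorMap`."""
    if gt.n_frames != est.n_frames:
        raise ValueError("trajectories must cover the same frame set")
    common = gt.valid & est.valid
    if common.sum() == 0:
        raise ValueError("no common valid frames")
    return _error_map_from_arrays(
        gt.cop_x[common],
        gt.cop_y[common],
        est.cop_x[common],
        est.cop_y[common],
        layout,
        grid,
        axis,
    )


def pooled_error_map(
    pairs: Sequence[tuple[CoPTrajectory, CoPTrajectory]],
    layout: InsoleLayout,
    grid: tuple[int, int] = (40, 20),
    axis: str = "XY",
) -> ErrorMap:
    """Error map pooled over several (ground truth, estimate) trajectory
    pairs, e.g. both feet of a subject in the canonical coordinate frame."""
    gx, gy, ex, ey = [], [], [], []
    for gt, est in pairs:
        common = gt.valid & est.valid
        gx.append(gt.cop_x[common])
        gy.append(gt.cop_y[common])
        ex.append(est.cop_x[common])
        ey.append(est.cop_y[common])
    gx, gy, ex, ey = map(np.concatenate, (gx, gy, ex, ey))
    if gx.size == 0:
        raise ValueError("no common valid frames")
    return _error_map_from_arrays(gx, gy, ex, ey, layout, grid, axis)


def _error_map_from_arrays(gx, gy, ex, ey, layout, grid, axis) -> ErrorMap:
    if axis not in AXES:
        raise ValueError(f"axis must be one of {AXES}")
    if axis == "X":
        err = np.abs(gx - ex)
    elif axis == "Y":
        err = np.abs(gy - ey)
    else:
        err = np.hypot(gx - ex, gy - ey)
    nx, ny = grid
    stat, x_edges, y_edges, _ = binned_statistic_2d(
        gx, gy, err, statistic="mean", bins=grid,
        range=[[0.0, layout.length], [0.0, layout.width]],
    )
    cnt, _, _, _ = binned_statistic_2d(
        gx, gy, err, statistic="count", bins=grid,
        range=[[0.0, layout.length], [0.0, layout.width]],
    )
    return ErrorMap(
        values=stat,
        counts=cnt.astype(int),
        x_edges=x_edges,
        y_edges=y_edges,
        clip_value=float(np.percentile(err, 99)),
        axis=axis,
    )


# ---------------------------------------------------------------------------
# optional matplotlib rendering (content mirrors of the three analyses)
# ---------------------------------------------------------------------------


def plot_convergence(curves: Mapping[str, OptimizationCurve], path) -> None:
    """Best-RMSE-vs-k curves with marginal-gain bars, one panel per target."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(curves), figsize=(5 * len(curves), 4), squeeze=False)
    for ax, (target, curve) in zip(axes[0], curves.items()):
        ks = sorted(curve.best)
        vals = [curve.metric(k) for k in ks]
        ax.plot(ks, vals, "o-", label=f"best RMSE CoP-{target}")
        mg = marginal_gains(curve)
        ax2 = ax.twinx()
        ax2.bar(list(mg.gains), list(mg.gains.values()), alpha=0.3, color="gray")
        ax.set_xlabel("number of sensors k")
        ax.set_ylabel("RMSE (mm)")
        ax2.set_ylabel("marginal gain (mm)")
        ax.set_title(f"CoP-{target}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_selection_frequency(freq: pd.DataFrame, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(freq.to_numpy(), aspect="auto", cmap="cividis")
    ax.set_xticks(range(freq.shape[1]), freq.columns)
    ax.set_yticks(range(freq.shape[0]), freq.index)
    ax.set_ylabel("sensor")
    fig.colorbar(im, ax=ax, label="selections across k")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_error_map(emap: ErrorMap, layout: InsoleLayout, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3.2))
    im = ax.pcolormesh(
        emap.x_edges, emap.y_edges, emap.clipped().T, cmap="inferno", shading="flat"
    )
    cents = layout.centroids()
    ax.plot(cents[:, 0], cents[:, 1], "wo", mfc="none")
    ax.set_xlabel("X (mm, posterior -> anterior)")
    ax.set_ylabel("Y (mm)")
    ax.set_title(f"mean |error| on {emap.axis} (clipped at {emap.clip_value:.1f} mm)")
    fig.colorbar(im, ax=ax, label="mm")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
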