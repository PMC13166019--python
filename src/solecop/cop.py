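"""Barycentric center-of-pressure reconstruction and error metrics.

The CoP at time t is the pressure-weighted barycenter of the sensor
centroids::

    CoP_x(t) = sum_i P_i(t) A_i x_i / sum_i P_i(t) A_i      (likewise y)

with the sum over the chosen sensor subset (excluded sensors get weight
zero). The full 16-sensor reconstruction serves as the ground-truth
reference for any reduced subset.

Frames whose subset carries (numerically) no load have an undefined
barycenter. Two fallback policies are offered:

* ``hold_last`` (default): repeat the last valid estimate within the same
  stance phase, marking the frame as substituted; frames before the first
  valid estimate of a phase stay invalid.
* ``exclude``: mark the frame invalid and drop it from the metrics.

Error metrics against the ground truth are the RMSE per axis, the global
Euclidean RMSE (root mean squared per-frame Euclidean distance, which equals
``sqrt(RMSE_X^2 + RMSE_Y^2)`` on a shared frame set), and the 95th
percentile (P95) of the per-frame error distribution as a worst-case
summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .geometry import N_SENSORS, InsoleLayout, sensor_ids
from .preprocess import PressureRecording
from .segment import StancePhase

#: Denominator threshold (N) below which a subset barycenter is undefined.
DENOM_EPS = 1e-12

FALLBACKS = ("hold_last", "exclude")
AXES = ("X", "Y", "XY")


@dataclass(frozen=True)
class SensorSubset:
    """A non-empty subset of sensor ids, representable as a 16-bit mask
    (bit i-1 set <=> sensor i is a member)."""

    members: tuple[int, ...]

    def __init__(self, members: Iterable[int]):
        object.__setattr__(self, "members", sensor_ids(members))

    @property
    def k(self) -> int:
        return len(self.members)

    @property
    def mask(self) -> int:
        m = 0
        for i in self.members:
            m |= 1 << (i - 1)
        return m

    @classmethod
    def from_mask(cls, mask: int) -> "SensorSubset":
        return cls(i + 1 for i in range(N_SENSORS) if mask >> i & 1)

    def bitstring(self) -> str:
        """16-character string, leftmost character = sensor 1."""
        return "".join("1" if (i + 1) in self.members else "0" for i in range(N_SENSORS))

    @classmethod
    def full(cls) -> "SensorSubset":
        return cls(range(1, N_SENSORS + 1))


@dataclass
class CoPTrajectory:
    """Per-frame CoP estimate over the pooled stance frames of a recording.

    ``valid`` marks frames carrying an estimate (true barycenter or held);
    ``substituted`` marks the held subset of those. Coordinates are NaN on
    invalid frames.
    """

    cop_x: np.ndarray  # mm
    cop_y: np.ndarray  # mm
    valid: np.ndarray  # bool
    substituted: np.ndarray  # bool, subset of valid
    frame_indices: np.ndarray  # indices into the source recording
    segment_ids: np.ndarray  # stance-phase index of each frame

    @property
    def n_frames(self) -> int:
        return self.cop_x.shape[0]


def phase_frames(phases: Sequence[StancePhase]) -> tuple[np.ndarray, np.ndarray]:
    """Concatenated frame indices of all phases plus a per-frame phase id."""
    if not phases:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    idx = np.concatenate([np.arange(p.start_frame, p.end_frame) for p in phases])
    seg = np.concatenate(
        [np.full(p.n_frames, i, dtype=int) for i, p in enumerate(phases)]
    )
    return idx, seg


def hold_last_fill(defined: np.ndarray, segment_ids: np.ndarray) -> np.ndarray:
    """Index of the defining frame for each position under zero-order hold
    within segments; -1 where no prior defined frame exists in the segment.

    ``defined`` may be 1-D (T,) or 2-D (B, T); ``segment_ids`` is (T,) and
    must be grouped (all frames of a segment contiguous).
    """
    defined = np.atleast_2d(defined)
    T = defined.shape[1]
    tidx = np.arange(T)
    seg_start = np.empty(T, dtype=int)
    if T:
        starts = np.r_[0, np.nonzero(np.diff(segment_ids) != 0)[0] + 1]
        seg_start = starts[np.searchsorted(starts, tidx, side="right") - 1]
    fill = np.maximum.accumulate(np.where(defined, tidx[None, :], -1), axis=1)
    fill[fill < seg_start[None, :]] = -1
    return fill


def compute_cop(
    rec: PressureRecording,
    layout: InsoleLayout,
    subset: SensorSubset | Iterable[int],
    phases: Sequence[StancePhase],
    fallback: str = "hold_last",
) -> CoPTrajectory:
    """Barycentric CoP trajectory of a sensor subset over the given phases."""
    if not isinstance(subset, SensorSubset):
        subset = SensorSubset(subset)
    if fallback not in FALLBACKS:
        raise ValueError(f"fallback must be one of {FALLBACKS}")
    idx, seg = phase_frames(phases)
    P = rec.frames[idx]
    if np.isnan(P).any():
        raise ValueError("recording contains missing samples; preprocess first")
    cols = [i - 1 for i in subset.members]
    w = P[:, cols] * layout.areas()[cols]
    cent = layout.centroids()[cols]
    denom = w.sum(axis=1)
    defined = denom > DENOM_EPS
    safe = np.where(defined, denom, 1.0)
    x = np.where(defined, (w @ cent[:, 0]) / safe, np.nan)
    y = np.where(defined, (w @ cent[:, 1]) / safe, np.nan)

    if fallback == "hold_last":
        fill = hold_last_fill(defined, seg)[0]
        valid = fill >= 0
        take = np.clip(fill, 0, None)
        x = np.where(valid, x[take], np.nan)
        y = np.where(valid, y[take], np.nan)
        substituted = valid & ~defined
    else:
        valid = defined
        substituted = np.zeros_like(valid)

    if valid.sum() == 0:
        raise ValueError("subset defines no valid CoP frame in the given phases")
    return CoPTrajectory(x, y, valid, substituted, idx, seg)


def _common_errors(
    gt: CoPTrajectory, est: CoPTrajectory, axis: str
) -> np.ndarray:
    if axis not in AXES:
        raise ValueError(f"axis must be one of {AXES}")
    if gt.n_frames != est.n_frames:
        raise ValueError("trajectories must cover the same frame set")
    common = gt.valid & est.valid
    if common.sum() == 0:
        raise ValueError("no frame is valid in both trajectories")
    dx = gt.cop_x[common] - est.cop_x[common]
    dy = gt.cop_y[common] - est.cop_y[common]
    if axis == "X":
        return np.abs(dx)
    if axis == "Y":
        return np.abs(dy)
    return np.hypot(dx, dy)


def rmse(gt: CoPTrajectory, est: CoPTrajectory, axis: str = "XY") -> float:
    """Root mean square error (mm) over frames valid in both trajectories."""
    err = _common_errors(gt, est, axis)
    return float(np.sqrt(np.mean(err**2)))


def p95_error(gt: CoPTrajectory, est: CoPTrajectory, axis: str = "XY") -> float:
    """95th percentile (mm, linear interpolation) of the per-frame error."""
    err = _common_errors(gt, est, axis)
    return float(np.percentile(err, 95))


def euclidean_rmse(rmse_x: float, rmse_y: float) -> float:
    """Combine per-axis RMSEs into the global Euclidean RMSE.

    On any shared frame set the per-frame Euclidean squared error is the sum
    of the per-axis squared errors, so RMSE_XY = sqrt(RMSE_X^2 + RMSE_Y^2).
    """
    return float(np.hypot(rmse_x, rmse_y))
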