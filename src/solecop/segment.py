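"""Gait segmentation: isolate validated stance phases from a recording.

A candidate ground contact is a maximal run of frames whose total vertical
force exceeds a threshold (default 15 N), flanked on both sides by at least
one sub-threshold (swing) frame — runs touching the recording edges are
discarded, so only complete, uninterrupted stances surrounded by swing are
kept. A candidate becomes a validated step when it additionally shows a
physiological heel-to-toe roll-over: the full-array CoP-X starts in the
posterior third of the insole, ends in the anterior third, and never regresses
backwards by more than a small tolerance (default 5% of insole length) —
strict frame-to-frame monotonicity would reject essentially every real
signal, so bounded backward excursion is used instead.

Steady-state cropping then discards the first and last validated step of a
recording, removing gait initiation and termination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import InsoleLayout, posterior_anterior_thirds
from .preprocess import PressureRecording


@dataclass(frozen=True)
class SegmentationParams:
    force_threshold: float = 15.0  # N
    min_duration: float = 200.0  # ms
    regression_tolerance: float = 0.05  # fraction of insole length

    def __post_init__(self) -> None:
        if self.force_threshold <= 0 or self.min_duration <= 0:
            raise ValueError("force_threshold and min_duration must be > 0")
        if self.regression_tolerance < 0:
            raise ValueError("regression_tolerance must be >= 0")


@dataclass(frozen=True)
class StancePhase:
    """Half-open frame interval [start_frame, end_frame) of one validated step."""

    start_frame: int
    end_frame: int
    duration_ms: float

    def __post_init__(self) -> None:
        if not self.start_frame < self.end_frame:
            raise ValueError("require start_frame < end_frame")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


def total_force(rec: PressureRecording, layout: InsoleLayout) -> np.ndarray:
    """Per-frame total vertical force F(t) = sum_i P_i(t) A_i in N.

    Requires a preprocessed (gap-free) recording.
    """
    if np.isnan(rec.frames).any():
        raise ValueError("recording contains missing samples; preprocess first")
    return rec.frames @ layout.areas()


def detect_contacts(
    force: np.ndarray, params: SegmentationParams, sample_rate: float
) -> list[tuple[int, int]]:
    """Maximal supra-threshold runs, kept when flanked by swing on both sides
    and at least ``min_duration`` long. Returns half-open frame intervals."""
    force = np.asarray(force, dtype=float)
    above = force > params.force_threshold
    if not above.any():
        return []
    d = np.diff(above.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    ends = list(np.nonzero(d == -1)[0] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(force))
    min_frames = int(round(params.min_duration * sample_rate / 1000.0))
    out = []
    for s, e in zip(starts, ends):
        if s == 0 or e == len(force):  # recording edge is not swing
            continue
        if e - s >= min_frames:
            out.append((s, e))
    return out


def check_rollover(
    cop_x: np.ndarray, layout: InsoleLayout, params: SegmentationParams
) -> bool:
    """True iff the CoP-X series shows a physiological heel-to-toe roll-over.

    Conditions: the first valid CoP-X lies in the posterior third, the last in
    the anterior third, and the maximal backward excursion (running max minus
    current value) stays within ``regression_tolerance * length``.
    """
    x = np.asarray(cop_x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("empty or all-invalid CoP-X series")
    post, ant = posterior_anterior_thirds(layout)
    if not (x[0] < post and x[-1] > ant):
        return False
    regression = np.max(np.maximum.accumulate(x) - x)
    return bool(regression <= params.regression_tolerance * layout.length)


def _fullset_cop_x(
    rec: PressureRecording, layout: InsoleLayout, start: int, end: int
) -> np.ndarray:
    """CoP-X over [start, end) from the full 16-sensor array."""
    w = rec.frames[start:end] * layout.areas()
    denom = w.sum(axis=1)
    x = layout.centroids()[:, 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, (w @ x) / denom, np.nan)


def segment_steps(
    rec: PressureRecording,
    layout: InsoleLayout,
    params: SegmentationParams | None = None,
) -> list[StancePhase]:
    """Validated stance phases: force-threshold candidates that also pass the
    roll-over check. Ordered and pairwise disjoint."""
    params = params or SegmentationParams()
    force = total_force(rec, layout)
    phases = []
    for s, e in detect_contacts(force, params, rec.sample_rate):
        cop_x = _fullset_cop_x(rec, layout, s, e)
        if check_rollover(cop_x, layout, params):
            phases.append(
                StancePhase(s, e, duration_ms=1000.0 * (e - s) / rec.sample_rate)
            )
    return phases


def crop_steady_state(phases: list[StancePhase]) -> list[StancePhase]:
    """Discard the first and last step (gait initiation/termination); fewer
    than three steps leave nothing analyzable."""
    if len(phases) < 3:
        return []
    return list(phases[1:-1])
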