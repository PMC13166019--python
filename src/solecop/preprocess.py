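"""Raw-recording container and signal cleaning.

Cleaning has two stages, applied in this order:

1. :func:`interpolate_missing` — short internal gaps (<= 5 frames by default)
   on each pressure channel are filled by linear interpolation between the
   flanking valid samples; longer gaps and gaps touching the recording edges
   are left missing.
2. :func:`hold_no_contact` — any sample still missing takes the last valid
   value on its channel (zero-order hold); leading missing samples, which
   have no prior value, are set to 0 (no contact). After this stage the
   recording contains no missing samples.

Both operations are idempotent and never alter a valid sample.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .geometry import N_SENSORS


@dataclass
class PressureRecording:
    """Multichannel plantar-pressure time series.

    ``frames`` is a (T, 16) float array of pressures in N cm^-2 with NaN
    marking missing samples; channel j (0-based) belongs to sensor j+1.
    """

    sample_rate: float  # Hz
    frames: np.ndarray  # (T, 16), N cm^-2, NaN = missing
    subject_id: str = "sim"
    side: str = "left"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if self.frames.ndim != 2 or self.frames.shape[1] != N_SENSORS:
            raise ValueError(f"frames must be (T, {N_SENSORS}), got {self.frames.shape}")
        with np.errstate(invalid="ignore"):
            if np.any(self.frames < 0):
                raise ValueError("non-missing pressures must be >= 0")

    @property
    def missing_mask(self) -> np.ndarray:
        """(T, 16) boolean mask, True where a sample is missing."""
        return np.isnan(self.frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def copy(self) -> "PressureRecording":
        return dataclasses.replace(self, frames=self.frames.copy())


def _nan_runs(col: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of NaN in a 1-D array."""
    isnan = np.isnan(col)
    if not isnan.any():
        return []
    d = np.diff(isnan.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    ends = list(np.nonzero(d == -1)[0] + 1)
    if isnan[0]:
        starts.insert(0, 0)
    if isnan[-1]:
        ends.append(len(col))
    return list(zip(starts, ends))


def interpolate_missing(rec: PressureRecording, max_gap: int = 5) -> PressureRecording:
    """Fill internal missing runs of length <= ``max_gap`` frames linearly.

    Runs longer than ``max_gap`` and runs touching either end of the
    recording are left missing (they carry no interpolation support on both
    sides, or are deemed too long to reconstruct).
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    out = rec.copy()
    T = out.n_frames
    for j in range(out.frames.shape[1]):
        col = out.frames[:, j]
        for start, end in _nan_runs(col):
            if start == 0 or end == T:  # edge gap: no flanking sample
                continue
            if end - start > max_gap:
                continue
            left, right = col[start - 1], col[end - 1 + 1]
            t = np.arange(1, end - start + 1, dtype=float) / (end - start + 1)
            col[start:end] = left + t * (right - left)
    return out


def hold_no_contact(rec: PressureRecording) -> PressureRecording:
    """Zero-order hold for channels with undetected contact.

    Every still-missing sample takes the last preceding valid value on its
    channel; leading missing samples become 0. The result has no missing
    samples.
    """
    out = rec.copy()
    T = out.n_frames
    idx = np.arange(T)[:, None]
    valid = ~np.isnan(out.frames)
    last_valid = np.maximum.accumulate(np.where(valid, idx, -1), axis=0)
    take = np.clip(last_valid, 0, None)
    filled = np.take_along_axis(out.frames, take, axis=0)
    filled[last_valid < 0] = 0.0
    out.frames = filled
    return out


def preprocess(rec: PressureRecording, max_gap: int = 5) -> PressureRecording:
    """Full cleaning pipeline: gap-limited interpolation, then hold."""
    return hold_no_contact(interpolate_missing(rec, max_gap=max_gap))
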