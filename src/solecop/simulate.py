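"""Seeded synthetic plantar-pressure gait generator.

The generator emulates the structure of straight-line, self-selected-speed
walking as seen by a 16-cell pressure insole sampled at 100 Hz:

* alternating stance (default 0.6 s) and swing (default 0.4 s) phases, with
  swing strictly zero-pressure;
* sequential heel -> toe activation: each functional zone carries a
  raised-cosine pressure pulse over its own window of the stance, so the
  per-sensor peak times follow the rearfoot -> midfoot -> forefoot -> toes
  order and the full-array CoP rolls over monotonically from the posterior
  to the anterior third of the insole;
* amplitudes normalized so the peak total vertical force matches the
  configured body weight;
* additive Gaussian sensor noise (clipped at zero) on loaded channels, and
  independent per-sample dropout marked as *missing* (NaN), exercising the
  interpolation/hold cleaning path.

Anomaly modes inject one non-physiological step that the segmentation
criteria must reject: ``shuffle`` (load pinned to the rearfoot, no roll-over),
``short_contact`` (150 ms ground contact, below the 200 ms minimum) and
``low_force`` (peak total force below the 15 N threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .geometry import N_SENSORS, ZONE_OF_SENSOR, InsoleLayout
from .preprocess import PressureRecording

ANOMALIES = ("none", "shuffle", "short_contact", "low_force")

#: Stance-fraction activation windows per zone (onset, offset). Chosen so the
#: zones overlap smoothly and peak in heel->toe order.
DEFAULT_ZONE_WINDOWS: dict[str, tuple[float, float]] = {
    "rearfoot": (0.00, 0.45),
    "midfoot": (0.15, 0.65),
    "forefoot": (0.35, 0.95),
    "toes": (0.55, 1.00),
}

#: Relative peak-pressure weights per zone (N cm^-2 before normalization to
#: body weight): heel-strike and push-off dominate, midfoot carries less.
DEFAULT_ZONE_SCALES: dict[str, float] = {
    "rearfoot": 12.0,
    "midfoot": 5.0,
    "forefoot": 12.0,
    "toes": 8.0,
}


@dataclass
class GaitSimConfig:
    """Parameters of one simulated walking recording."""

    n_steps: int = 10
    sample_rate: float = 100.0  # Hz
    stance_duration: float = 0.6  # s
    swing_duration: float = 0.4  # s
    body_weight: float = 720.0  # N (~73 kg subject)
    zone_onset_offset: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ZONE_WINDOWS)
    )
    peak_pressure_scale: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ZONE_SCALES)
    )
    noise_sd: float = 0.05  # N cm^-2, on loaded channels during stance
    missing_prob: float = 0.01  # independent per-sample dropout probability
    onset_jitter: float = 0.02  # per-sensor window jitter, stance fraction
    seed: int = 0
    anomaly: str = "none"
    anomaly_step: int | None = None  # default: middle step
    active_sensors: Sequence[int] | None = None  # default: all 16

    def __post_init__(self) -> None:
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.stance_duration <= 0 or self.swing_duration <= 0:
            raise ValueError("durations must be > 0")
        if not 0 <= self.missing_prob < 1:
            raise ValueError("missing_prob must be in [0, 1)")
        if self.anomaly not in ANOMALIES:
            raise ValueError(f"anomaly must be one of {ANOMALIES}")
        for zone, (on, off) in self.zone_onset_offset.items():
            if not 0 <= on < off <= 1:
                raise ValueError(f"zone {zone}: require 0 <= onset < offset <= 1")
        ron = self.zone_onset_offset["rearfoot"][0]
        ton = self.zone_onset_offset["toes"][0]
        if not ron < ton:
            raise ValueError("rearfoot must activate before the toes (heel strikes first)")


def activation_profile(onset: float, offset: float, t) -> np.ndarray | float:
    """Raised-cosine activation pulse on the stance-fraction axis.

    Zero outside ``[onset, offset]``, smooth and unimodal inside with value 1
    at the interval midpoint: ``0.5 * (1 - cos(2 pi (t - onset) / (offset - onset)))``.
    """
    if not onset < offset:
        raise ValueError("require onset < offset")
    t_arr = np.asarray(t, dtype=float)
    u = (t_arr - onset) / (offset - onset)
    w = np.where((u >= 0) & (u <= 1), 0.5 * (1.0 - np.cos(2.0 * np.pi * u)), 0.0)
    return float(w) if np.isscalar(t) else w


def _stance_template(
    config: GaitSimConfig, layout: InsoleLayout, rng: np.random.Generator, n_frames: int
) -> np.ndarray:
    """Noise-free (n_frames, 16) single-stance pressure block, scaled so the
    peak total force equals the configured body weight."""
    active = set(config.active_sensors) if config.active_sensors is not None else set(
        range(1, N_SENSORS + 1)
    )
    tau = np.arange(n_frames, dtype=float) / max(n_frames - 1, 1)
    block = np.zeros((n_frames, N_SENSORS))
    # rng draws are made for every sensor so that the stream (and thus the
    # whole recording) does not depend on which sensors are active
    for sid in range(1, N_SENSORS + 1):
        jit_on, jit_off = rng.uniform(-config.onset_jitter, config.onset_jitter, size=2)
        gain = rng.uniform(0.9, 1.1)
        if sid not in active:
            continue
        zone = ZONE_OF_SENSOR[sid]
        on, off = config.zone_onset_offset[zone]
        on = float(np.clip(on + jit_on, 0.0, 0.98))
        off = float(np.clip(off + jit_off, on + 0.02, 1.0))
        block[:, sid - 1] = config.peak_pressure_scale[zone] * gain * activation_profile(
            on, off, tau
        )
    force = block @ layout.areas()  # N, per frame
    peak = force.max()
    if peak > 0:
        block *= config.body_weight / peak
    return block


def simulate_recording(config: GaitSimConfig, layout: InsoleLayout) -> PressureRecording:
    """Generate one seeded recording: swing, then ``n_steps`` x (stance, swing).

    With ``anomaly='none'`` every stance satisfies both segmentation criteria
    (total force > 15 N for >= 200 ms; posterior-to-anterior monotone CoP-X
    roll-over); otherwise the designated anomaly step violates exactly one of
    them. Identical (config, layout) give bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.sample_rate
    stance_n = int(round(config.stance_duration * fs))
    swing_n = int(round(config.swing_duration * fs))
    T = swing_n + config.n_steps * (stance_n + swing_n)
    frames = np.zeros((T, N_SENSORS))

    base = _stance_template(config, layout, rng, stance_n)
    anomaly_step = (
        config.anomaly_step if config.anomaly_step is not None else config.n_steps // 2
    )

    rearfoot_cols = [i - 1 for i in range(1, N_SENSORS + 1) if ZONE_OF_SENSOR[i] == "rearfoot"]
    loaded = base.max(axis=0) > 0  # channels that ever carry pressure

    for s in range(config.n_steps):
        start = swing_n + s * (stance_n + swing_n)
        amp = rng.uniform(0.97, 1.03)
        block = base * amp
        if config.anomaly != "none" and s == anomaly_step:
            if config.anomaly == "shuffle":
                shuffled = np.zeros_like(block)
                shuffled[:, rearfoot_cols] = block[:, rearfoot_cols]
                block = shuffled
            elif config.anomaly == "low_force":
                block = block * (10.0 / config.body_weight)  # peak ~10 N < threshold
            elif config.anomaly == "short_contact":
                m = max(int(round(0.15 * fs)), 2)  # 150 ms of contact
                short = _resample_template(base, m) * amp
                block = np.zeros_like(block)
                block[:m] = short
        noise = rng.normal(0.0, config.noise_sd, size=block.shape)
        block = block + np.where(loaded[None, :] & (block > 0), noise, 0.0)
        frames[start : start + stance_n] = np.clip(block, 0.0, None)

    if config.missing_prob > 0:
        drop = rng.random(frames.shape) < config.missing_prob
        frames[drop] = np.nan

    return PressureRecording(
        sample_rate=fs, frames=frames, subject_id=f"sim{config.seed:04d}", side=layout.side
    )


def _resample_template(base: np.ndarray, m: int) -> np.ndarray:
    """Linearly resample a stance block to m frames (time compression)."""
    n = base.shape[0]
    src = np.linspace(0, n - 1, m)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n - 1)
    w = (src - lo)[:, None]
    return base[lo] * (1 - w) + base[hi] * w
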