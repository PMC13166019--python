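"""End-to-end orchestration: simulate -> preprocess -> segment -> optimize
-> report, with a hashed artifact manifest for reproducibility."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as sio
from .cop import SensorSubset, compute_cop
from .geometry import InsoleLayout, load_layout, mirror_layout
from .preprocess import preprocess
from .report import (
    cross_performance,
    marginal_gains,
    pooled_error_map,
    selection_frequency,
)
from .search import best_per_k, evaluate_subsets, pool_frames
from .segment import SegmentationParams, crop_steady_state, segment_steps
from .simulate import GaitSimConfig, simulate_recording

TARGETS = ("X", "Y", "XY")


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    outdir: Path
    layout_path: Path | None = None  # None -> bundled default left layout
    seed: int = 0
    n_steps: int = 20
    sides: tuple[str, ...] = ("left", "right")
    anomaly: str = "none"
    k_range: tuple[int, int] = (1, 16)
    fallback: str = "hold_last"
    gain_threshold: float = 1.5  # mm
    grid: tuple[int, int] = (40, 20)
    map_k: int = 5  # subset size for the error maps
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    active_sensors: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.gain_threshold <= 0:
            raise ValueError("gain_threshold must be > 0")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns the artifact manifest.

    Identical configuration (including seed) yields bit-identical artifact
    hashes.
    """
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    left = load_layout(cfg.layout_path)
    files: list[Path] = []

    pooled_inputs = []
    step_counts = {}
    for i, side in enumerate(cfg.sides):
        layout = left if side == "left" else mirror_layout(left)
        sim = GaitSimConfig(
            n_steps=cfg.n_steps,
            seed=cfg.seed + i,
            anomaly=cfg.anomaly,
            active_sensors=cfg.active_sensors,
        )
        raw = simulate_recording(sim, layout)
        clean = preprocess(raw)
        phases = segment_steps(clean, layout, cfg.segmentation)
        kept = crop_steady_state(phases)
        step_counts[side] = {"detected": len(phases), "retained": len(kept)}
        for path, writer, obj in (
            (cfg.outdir / f"recording_{side}.csv", sio.write_recording, raw),
            (cfg.outdir / f"preprocessed_{side}.csv", sio.write_recording, clean),
        ):
            writer(path, obj)
            files.append(path)
        steps_path = cfg.outdir / f"steps_{side}.csv"
        sio.write_steps(steps_path, kept, subject_id=clean.subject_id)
        files.append(steps_path)
        pooled_inputs.append((clean, layout, kept))

    pool = pool_frames(pooled_inputs)
    evals = evaluate_subsets(pool, k_range=cfg.k_range, fallback=cfg.fallback)
    evals_path = cfg.outdir / "evaluations.csv"
    sio.write_evaluations(evals_path, evals)
    files.append(evals_path)

    curves = {t: best_per_k(evals, t) for t in TARGETS}
    for t, curve in curves.items():
        p = cfg.outdir / f"curve_{t}.csv"
        sio.write_curve(p, curve)
        files.append(p)
        g = marginal_gains(curve, cfg.gain_threshold)
        p = cfg.outdir / f"gains_{t}.csv"
        sio.write_gains(p, g)
        files.append(p)

    k_lo, k_hi = cfg.k_range
    freq_lo, freq_hi = max(2, k_lo), min(15, k_hi)
    if freq_hi >= freq_lo:
        freq = selection_frequency(curves, (freq_lo, freq_hi))
        p = cfg.outdir / "selection_frequency.csv"
        freq.to_csv(p)
        files.append(p)

    if k_lo <= cfg.map_k <= k_hi:
        cross = cross_performance(evals, cfg.map_k)
        p = cfg.outdir / f"cross_performance_k{cfg.map_k}.csv"
        cross.to_csv(p)
        files.append(p)
        files += _write_error_maps(cfg, curves, pooled_inputs, left)

    manifest = sio.write_manifest(
        cfg.outdir / "manifest.json",
        files,
        params={
            "seed": cfg.seed,
            "n_steps": cfg.n_steps,
            "sides": list(cfg.sides),
            "k_range": list(cfg.k_range),
            "fallback": cfg.fallback,
            "force_threshold_N": cfg.segmentation.force_threshold,
            "min_duration_ms": cfg.segmentation.min_duration,
            "gain_threshold_mm": cfg.gain_threshold,
            "step_counts": step_counts,
        },
    )
    return manifest


def _write_error_maps(cfg, curves, pooled_inputs, left: InsoleLayout) -> list[Path]:
    """Error maps comparing the XY-optimal and Y-optimal layouts at map_k,
    on all three axes, pooled over feet in the left coordinate frame."""
    files = []
    for label, subset in (
        ("xyopt", curves["XY"].best[cfg.map_k].subset),
        ("yopt", curves["Y"].best[cfg.map_k].subset),
    ):
        pairs = []
        for rec, layout, phases in pooled_inputs:
            gt = compute_cop(rec, layout, SensorSubset.full(), phases, cfg.fallback)
            est = compute_cop(rec, layout, subset, phases, cfg.fallback)
            pairs.append((gt, est))
        for axis in TARGETS:
            emap = pooled_error_map(pairs, left, cfg.grid, axis)
            p = cfg.outdir / f"error_map_k{cfg.map_k}_{label}_{axis}.csv"
            sio.write_error_map(p, emap)
            files.append(p)
    return files
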