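"""Readers and writers for the pipeline's delimited-text file contracts.

Canonical recording file: CSV with header ``time_s, s01..s16`` (pressures in
N cm^-2), empty fields marking missing samples, preceded by ``#``-comment
metadata lines (sample rate, subject, side). All other artifacts are plain
CSV tables. Every writer/reader pair round-trips losslessly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import N_SENSORS
from .preprocess import PressureRecording
from .report import ErrorMap, MarginalGainSeries
from .search import OptimizationCurve, SensorSubset
from .segment import StancePhase

_SENSOR_COLS = [f"s{i:02d}" for i in range(1, N_SENSORS + 1)]


def write_recording(path: str | Path, rec: PressureRecording) -> None:
    path = Path(path)
    t = np.arange(rec.n_frames) / rec.sample_rate
    df = pd.DataFrame(rec.frames, columns=_SENSOR_COLS)
    df.insert(0, "time_s", t)
    with open(path, "w") as fh:
        fh.write(f"# sample_rate_hz: {rec.sample_rate}\n")
        fh.write(f"# subject_id: {rec.subject_id}\n")
        fh.write(f"# side: {rec.side}\n")
        df.to_csv(fh, index=False, na_rep="")


def read_recording(path: str | Path) -> PressureRecording:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line.lstrip("# ").partition(":")
            meta[key.strip()] = val.strip()
    df = pd.read_csv(path, comment="#")
    return PressureRecording(
        sample_rate=float(meta.get("sample_rate_hz", 100.0)),
        frames=df[_SENSOR_COLS].to_numpy(dtype=float),
        subject_id=meta.get("subject_id", "unknown"),
        side=meta.get("side", "left"),
    )


def write_steps(
    path: str | Path, phases: Sequence[StancePhase], subject_id: str = "sim"
) -> None:
    rows = [
        {
            "subject_id": subject_id,
            "step_index": i,
            "start_frame": p.start_frame,
            "end_frame": p.end_frame,
            "duration_ms": p.duration_ms,
        }
        for i, p in enumerate(phases)
    ]
    pd.DataFrame(
        rows, columns=["subject_id", "step_index", "start_frame", "end_frame", "duration_ms"]
    ).to_csv(path, index=False)


def read_steps(path: str | Path) -> list[StancePhase]:
    df = pd.read_csv(path)
    return [
        StancePhase(int(r.start_frame), int(r.end_frame), float(r.duration_ms))
        for r in df.itertuples()
    ]


def write_evaluations(path: str | Path, evaluations: pd.DataFrame) -> None:
    df = evaluations.copy()
    df.insert(
        0, "subset", [SensorSubset.from_mask(int(m)).bitstring() for m in df.pop("mask")]
    )
    df.to_csv(path, index=False)


def read_evaluations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subset": str})
    df.insert(0, "mask", [SensorSubset(
        i + 1 for i, c in enumerate(bits) if c == "1").mask for bits in df.pop("subset")])
    return df


def write_curve(path: str | Path, curve: OptimizationCurve) -> None:
    rows = []
    for k in sorted(curve.best):
        ev = curve.best[k]
        rows.append(
            {
                "k": k,
                "sensors": ";".join(str(i) for i in ev.subset.members),
                "rmse_x": ev.rmse_x,
                "rmse_y": ev.rmse_y,
                "rmse_xy": ev.rmse_xy,
                "p95_x": ev.p95_x,
                "p95_y": ev.p95_y,
                "p95_xy": ev.p95_xy,
                "coverage": ev.coverage,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_gains(path: str | Path, gains: MarginalGainSeries) -> None:
    df = pd.DataFrame(
        {"k": sorted(gains.gains), "gain_mm": [gains.gains[k] for k in sorted(gains.gains)]}
    )
    df["target"] = gains.target
    df["threshold_mm"] = gains.threshold
    df["inflection_k"] = gains.inflection_k if gains.inflection_k is not None else ""
    df.to_csv(path, index=False)


def write_error_map(path: str | Path, emap: ErrorMap) -> None:
    """Long-format grid: one row per cell with centers, value and count."""
    nx, ny = emap.values.shape
    xc = 0.5 * (emap.x_edges[:-1] + emap.x_edges[1:])
    yc = 0.5 * (emap.y_edges[:-1] + emap.y_edges[1:])
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    pd.DataFrame(
        {
            "x_bin": ix.ravel(),
            "y_bin": iy.ravel(),
            "x_center_mm": xc[ix.ravel()],
            "y_center_mm": yc[iy.ravel()],
            "mean_abs_error_mm": emap.values.ravel(),
            "n_frames": emap.counts.ravel(),
            "clip_value_mm": emap.clip_value,
            "axis": emap.axis,
        }
    ).to_csv(path, index=False, na_rep="")


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def write_manifest(path: str | Path, files: Sequence[Path], params: Mapping) -> dict:
    manifest = {
        "parameters": dict(params),
        "files": {p.name: sha256_file(p) for p in sorted(files)},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
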