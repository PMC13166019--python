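"""Exhaustive combinatorial sensor-subset search.

All 2^16 - 1 = 65,535 non-empty subsets of the 16-sensor array are evaluated
against the full-array ground truth (the size-16 subset itself is the
zero-error reference row). For speed, per-frame moment triples
(P_i A_i, P_i A_i x_i, P_i A_i y_i) are precomputed once; each subset's CoP
then needs only a masked sum over members, evaluated here in vectorized
chunks. The strategy is required to be numerically equivalent to a naive
per-subset recomputation loop.

Optimization targets: antero-posterior accuracy (RMSE on CoP-X),
medio-lateral accuracy (RMSE on CoP-Y), and global accuracy (Euclidean
RMSE on CoP-XY). ``best_per_k`` selects, per subset size k, the subset
minimizing the target metric; ties are broken by the lexicographically
smallest sorted id tuple, which makes the argmin total and the whole search
deterministic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .cop import DENOM_EPS, SensorSubset, hold_last_fill
from .geometry import InsoleLayout
from .preprocess import PressureRecording
from .segment import StancePhase

EVAL_COLUMNS = (
    "mask",
    "k",
    "rmse_x",
    "rmse_y",
    "rmse_xy",
    "p95_x",
    "p95_y",
    "p95_xy",
    "coverage",
)


@dataclass
class PooledFrames:
    """Per-frame moment triples pooled over recordings, phases and feet.

    ``m0[t, i] = P_i(t) A_i`` (N), ``mx`` and ``my`` additionally weighted by
    the centroid coordinates (N mm). The ground-truth CoP is the full-array
    barycenter. ``segment_ids`` index the originating stance phase; the
    hold-last fallback never crosses a phase boundary.
    """

    m0: np.ndarray  # (T, n)
    mx: np.ndarray  # (T, n)
    my: np.ndarray  # (T, n)
    gt_x: np.ndarray  # (T,)
    gt_y: np.ndarray  # (T,)
    segment_ids: np.ndarray  # (T,)
    n_sensors: int

    @property
    def n_frames(self) -> int:
        return self.m0.shape[0]


def pool_frames(
    recordings: Sequence[tuple[PressureRecording, InsoleLayout, Sequence[StancePhase]]],
) -> PooledFrames:
    """Pool the retained stance frames of one or more recordings.

    Each recording is evaluated against its own layout (a right-foot
    recording against the mirrored layout), so errors pool in mm across feet
    and sizes.
    """
    m0s, mxs, mys, segs = [], [], [], []
    seg_offset = 0
    for rec, layout, phases in recordings:
        if np.isnan(rec.frames).any():
            raise ValueError("recording contains missing samples; preprocess first")
        for j, p in enumerate(phases):
            P = rec.frames[p.start_frame : p.end_frame]
            w = P * layout.areas()
            m0s.append(w)
            mxs.append(w * layout.centroids()[:, 0])
            mys.append(w * layout.centroids()[:, 1])
            segs.append(np.full(P.shape[0], seg_offset + j, dtype=int))
        seg_offset += len(phases)
    if not m0s:
        raise ValueError("no retained stance frames to pool")
    m0 = np.vstack(m0s)
    mx = np.vstack(mxs)
    my = np.vstack(mys)
    denom = m0.sum(axis=1)
    if np.any(denom <= DENOM_EPS):
        raise ValueError("a pooled frame carries no load on the full array")
    return PooledFrames(
        m0=m0,
        mx=mx,
        my=my,
        gt_x=mx.sum(axis=1) / denom,
        gt_y=my.sum(axis=1) / denom,
        segment_ids=np.concatenate(segs),
        n_sensors=m0.shape[1],
    )


def enumerate_subsets(
    n: int = 16, k_range: tuple[int, int] = (1, 16)
) -> Iterator[SensorSubset]:
    """Yield every subset of {1..n} with k in ``k_range`` exactly once,
    ordered by k then lexicographically. All k from 1 to 16 give the full
    2^16 - 1 = 65,535 subsets (the size-16 set is the reference row)."""
    k_lo, k_hi = k_range
    if not 1 <= k_lo <= k_hi <= n:
        raise ValueError(f"invalid k_range {k_range} for n={n}")
    for k in range(k_lo, k_hi + 1):
        for combo in itertools.combinations(range(1, n + 1), k):
            yield SensorSubset(combo)


def _masked_rms(sq: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Row-wise sqrt(mean of sq over valid); NaN for empty rows."""
    cnt = valid.sum(axis=1)
    s = np.where(valid, sq, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(cnt > 0, np.sqrt(s / cnt), np.nan)


def _masked_p95(err: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Row-wise 95th percentile (linear interpolation) of err over valid."""
    B = err.shape[0]
    x = np.where(valid, err, np.nan)
    x = np.sort(x, axis=1)  # NaN sorts last
    cnt = valid.sum(axis=1)
    out = np.full(B, np.nan)
    ok = cnt > 0
    pos = 0.95 * (cnt[ok] - 1)
    lo = np.floor(pos).astype(int)
    hi = np.ceil(pos).astype(int)
    rows = np.nonzero(ok)[0]
    xlo = x[rows, lo]
    xhi = x[rows, hi]
    out[ok] = xlo + (pos - lo) * (xhi - xlo)
    return out


def evaluate_subsets(
    pool: PooledFrames,
    subsets: Iterable[SensorSubset] | None = None,
    k_range: tuple[int, int] = (1, 16),
    fallback: str = "hold_last",
    chunk_size: int = 2048,
) -> pd.DataFrame:
    """Evaluate subsets against the pooled ground truth.

    Returns one row per subset with RMSE and P95 per axis (mm) and the
    coverage, i.e. the fraction of frames whose subset barycenter is defined
    without fallback. Subsets with no valid frame at all get NaN metrics and
    coverage 0. Results are independent of evaluation order and bitwise
    deterministic.
    """
    if fallback not in ("hold_last", "exclude"):
        raise ValueError("fallback must be 'hold_last' or 'exclude'")
    if subsets is None:
        subsets = enumerate_subsets(pool.n_sensors, k_range)
    masks = np.array([s.mask for s in subsets], dtype=np.int64)
    T = pool.n_frames
    tidx = np.arange(T)
    rows = []
    for lo in range(0, masks.size, chunk_size):
        mchunk = masks[lo : lo + chunk_size]
        B = mchunk.size
        memb = ((mchunk[:, None] >> np.arange(pool.n_sensors)[None, :]) & 1).astype(
            float
        )  # (B, n)
        denom = memb @ pool.m0.T  # (B, T)
        num_x = memb @ pool.mx.T
        num_y = memb @ pool.my.T
        defined = denom > DENOM_EPS
        safe = np.where(defined, denom, 1.0)
        ex = np.where(defined, num_x / safe, 0.0)
        ey = np.where(defined, num_y / safe, 0.0)
        if fallback == "hold_last":
            fill = hold_last_fill(defined, pool.segment_ids)
            valid = fill >= 0
            take = np.clip(fill, 0, None)
            ex = np.take_along_axis(ex, take, axis=1)
            ey = np.take_along_axis(ey, take, axis=1)
        else:
            valid = defined
        dx2 = np.where(valid, (ex - pool.gt_x[None, :]) ** 2, 0.0)
        dy2 = np.where(valid, (ey - pool.gt_y[None, :]) ** 2, 0.0)
        rmse_x = _masked_rms(dx2, valid)
        rmse_y = _masked_rms(dy2, valid)
        rmse_xy = _masked_rms(dx2 + dy2, valid)
        p95_x = _masked_p95(np.sqrt(dx2), valid)
        p95_y = _masked_p95(np.sqrt(dy2), valid)
        p95_xy = _masked_p95(np.sqrt(dx2 + dy2), valid)
        coverage = defined.mean(axis=1)
        kvals = np.array([bin(int(m)).count("1") for m in mchunk])
        rows.append(
            pd.DataFrame(
                {
                    "mask": mchunk,
                    "k": kvals,
                    "rmse_x": rmse_x,
                    "rmse_y": rmse_y,
                    "rmse_xy": rmse_xy,
                    "p95_x": p95_x,
                    "p95_y": p95_y,
                    "p95_xy": p95_xy,
                    "coverage": coverage,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class SubsetEvaluation:
    """Metrics of one subset (all distances in mm)."""

    subset: SensorSubset
    k: int
    rmse_x: float
    rmse_y: float
    rmse_xy: float
    p95_x: float
    p95_y: float
    p95_xy: float
    coverage: float


@dataclass
class OptimizationCurve:
    """Per-k optimum for one target ('X', 'Y' or 'XY')."""

    target: str
    best: dict[int, SubsetEvaluation]

    def metric(self, k: int) -> float:
        ev = self.best[k]
        return getattr(ev, f"rmse_{self.target.lower()}")


def metric_column(target: str) -> str:
    if target not in ("X", "Y", "XY"):
        raise ValueError("target must be 'X', 'Y' or 'XY'")
    return f"rmse_{target.lower()}"


def best_per_k(evaluations: pd.DataFrame, target: str) -> OptimizationCurve:
    """Select, for each subset size k present, the subset minimizing the
    target metric; exact metric ties resolve to the lexicographically
    smallest sorted id tuple."""
    col = metric_column(target)
    best: dict[int, SubsetEvaluation] = {}
    for k, grp in evaluations.groupby("k"):
        grp = grp.dropna(subset=[col])
        if grp.empty:
            raise ValueError(f"no evaluable subset of size k={k}")
        m = grp[col].min()
        cands = grp[grp[col] == m]
        chosen = min(
            cands.itertuples(),
            key=lambda r: SensorSubset.from_mask(int(r.mask)).members,
        )
        best[int(k)] = SubsetEvaluation(
            subset=SensorSubset.from_mask(int(chosen.mask)),
            k=int(k),
            rmse_x=float(chosen.rmse_x),
            rmse_y=float(chosen.rmse_y),
            rmse_xy=float(chosen.rmse_xy),
            p95_x=float(chosen.p95_x),
            p95_y=float(chosen.p95_y),
            p95_xy=float(chosen.p95_xy),
            coverage=float(chosen.coverage),
        )
    return OptimizationCurve(target=target, best=best)
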