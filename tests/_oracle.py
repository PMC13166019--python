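"""Naive per-subset reference implementation used to cross-check the
vectorized search: explicit Python loops over frames and sensors, sharing no
code with the production path."""

import itertools
import math

import numpy as np


def naive_evaluate(P, areas, cents, segment_ids, members, fallback="hold_last",
                   eps=1e-12):
    """Metrics of one subset from raw pressures via an explicit loop.

    P: (T, n) pressures; areas: (n,) cm^2; cents: (n, 2) mm; members:
    1-based sensor ids. Returns dict with rmse/p95 per axis and coverage.
    """
    T, n = P.shape
    # ground truth: all sensors
    gt = []
    for t in range(T):
        sw = sx = sy = 0.0
        for i in range(n):
            w = P[t, i] * areas[i]
            sw += w
            sx += w * cents[i, 0]
            sy += w * cents[i, 1]
        gt.append((sx / sw, sy / sw))

    est = [None] * T
    defined = [False] * T
    last = None
    last_seg = None
    for t in range(T):
        if last_seg is not None and segment_ids[t] != last_seg:
            last = None
        last_seg = segment_ids[t]
        sw = sx = sy = 0.0
        for i in members:
            w = P[t, i - 1] * areas[i - 1]
            sw += w
            sx += w * cents[i - 1, 0]
            sy += w * cents[i - 1, 1]
        if sw > eps:
            est[t] = (sx / sw, sy / sw)
            defined[t] = True
            last = est[t]
        elif fallback == "hold_last" and last is not None:
            est[t] = last

    dx = [gt[t][0] - est[t][0] for t in range(T) if est[t] is not None]
    dy = [gt[t][1] - est[t][1] for t in range(T) if est[t] is not None]
    if not dx:
        nan = float("nan")
        return {k: nan for k in
                ("rmse_x", "rmse_y", "rmse_xy", "p95_x", "p95_y", "p95_xy")} | {
                   "coverage": 0.0}

    def rms(vals):
        return math.sqrt(sum(v * v for v in vals) / len(vals))

    def p95(vals):
        return float(np.percentile(np.abs(vals), 95))

    dist = [math.hypot(a, b) for a, b in zip(dx, dy)]
    return {
        "rmse_x": rms(dx),
        "rmse_y": rms(dy),
        "rmse_xy": rms(dist),
        "p95_x": p95(dx),
        "p95_y": p95(dy),
        "p95_xy": p95(dist),
        "coverage": sum(defined) / T,
    }


def all_subsets(n):
    for k in range(1, n + 1):
        yield from itertools.combinations(range(1, n + 1), k)
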