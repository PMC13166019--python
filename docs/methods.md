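# Methods

## Coordinate frame and geometry

All positions are in mm with the origin at the posterior-medial corner of the
insole bounding box: X increases anteriorly (heel → toe), Y laterally. Right
insoles use a mirrored sensor numbering, so right-foot recordings are analyzed
against the mirrored layout (`mirror_layout`, an exact involution:
y → width − y); errors from both feet then pool directly in mm in a single
left-handed frame.

The bundled layout (`data/left_layout_synthetic.yaml`) is a synthetic fixture:
the commercial insole's true cell centroids and areas are not published.
It follows the standard anatomical partition — rearfoot 1–4, midfoot 5–8,
metatarsal heads 9–13, toes 14–16 — on a 270 × 90 mm bounding box with
~121 cm² of sensing area (about two thirds of a size 42–43 insole surface).
Every analysis accepts any layout file with the same schema, and each
recording is evaluated against its own layout, so per-size coordinates never
need cross-normalization.

## Synthetic gait generator

The generator stands in for human walking data and defines the study
conditions of the test suite. One recording is swing (0.4 s), then `n_steps`
× (stance 0.6 s + swing 0.4 s) at 100 Hz — a ~1 s stride, typical of
self-selected walking speed. Within a stance, each functional zone carries a
raised-cosine pressure pulse `½(1 − cos 2π(τ−on)/(off−on))` over its own
stance-fraction window (rearfoot 0–0.45, midfoot 0.15–0.65, forefoot
0.35–0.95, toes 0.55–1.0), with ±0.02 per-sensor window jitter and ±10%
per-sensor gain variation. This is the simplest smooth model that reproduces
the sequential heel → arch → metatarsal → hallux activation of real insole
traces and yields a posterior-to-anterior monotone full-array CoP-X roll-over.
Pulse amplitudes are rescaled so the noise-free peak total force equals the
configured body weight (default 720 N, a ~73 kg adult); per-step amplitude
varies by ±3%.

Measurement imperfections: additive Gaussian noise (default SD 0.05 N·cm⁻²,
clipped at zero) on loaded channels during stance — channels that never make
contact stay exactly zero, as a capacitive cell under no load reads zero —
and independent per-sample dropout (default probability 0.01) marked as
missing, which exercises the interpolation/hold path. Swing frames are
strictly zero. All randomness flows from one `numpy` generator seeded from
the config, so identical configs give bit-identical recordings.

Anomaly modes inject exactly one non-physiological step (the middle one by
default): `shuffle` restricts load to the rearfoot (no roll-over),
`short_contact` compresses ground contact to 150 ms, `low_force` scales the
step to a ~10 N peak. Each violates exactly one segmentation criterion.

What the generator does **not** emulate: subject-specific pressure
magnitudes and timing, double support and bilateral coupling, speed
variation, fatigue or pathology, sensor hysteresis and drift. Passing tests
therefore demonstrate the correctness and internal consistency of the
pipeline — segmentation logic, barycenter algebra, search optimality — not
that any particular sparse layout is optimal for real feet; optimal subsets
found on synthetic data reflect the simulated pressure patterns only.

## Preprocessing

Missing samples are filled in two stages, in this order: (1) linear
interpolation of internal gaps up to 5 frames (50 ms at 100 Hz) — longer
gaps and gaps touching the recording edges are left untouched, as they lack
reliable support; (2) zero-order hold of whatever remains, with leading
missing runs set to 0 (no contact detected before the first valid sample).
Interpolation first is the deliberate precedence: it is the more informative
fill, the hold is the fallback. "No contact" is operationalized as "still
missing after interpolation"; no per-channel contact threshold is applied.
Both stages are idempotent and never modify a valid sample; their composition
leaves no missing data.

## Segmentation

Total vertical force is F(t) = Σᵢ Pᵢ(t)·Aᵢ (N·cm⁻² × cm² = N). A candidate
contact is a maximal run with F strictly above 15 N, flanked by at least one
sub-threshold frame on each side — recording edges do not count as swing, so
truncated first/last contacts can never enter the analysis — and lasting at
least 200 ms (20 whole frames at 100 Hz).

A candidate becomes a validated step if the full-array CoP-X shows a
physiological roll-over: first value in the posterior third (< L/3), last in
the anterior third (> 2L/3), and maximal backward excursion (running maximum
minus current value) at most 5% of insole length. Strict frame-to-frame
monotonicity would reject essentially every noisy real signal; the bounded
regression rule is the documented stand-in, and the 5% default is
configurable. Steady-state cropping then drops the first and last validated
step of each recording; fewer than three steps leave nothing.

## CoP engine

The barycenter denominator Σ Pᵢ·Aᵢ is compared against ε = 1e−12 N: below
it the subset defines no barycenter for that frame. Two policies handle such
frames. The default, `hold_last`, repeats the last valid estimate within the
same stance phase (never across phases) and flags the frame as substituted;
frames before a phase's first valid estimate stay invalid. The alternative,
`exclude`, drops the frames from the metrics. `hold_last` is the default
because small subsets legitimately lose contact for parts of stance, and
finite worst-case errors for k ≤ 3 require those frames to stay in the error
pool rather than silently vanish; the fraction of frames not needing fallback
is always reported as `coverage`.

RMSE is pooled once over all retained frames of all recordings and both
feet — not averaged per subject — and P95 uses the linear-interpolation
percentile definition. On a shared valid-frame set the global metric obeys
RMSE_XY² = RMSE_X² + RMSE_Y² exactly, which the suite enforces.

## Exhaustive search

Per-frame moment triples (Pᵢ Aᵢ, Pᵢ Aᵢ xᵢ, Pᵢ Aᵢ yᵢ) are precomputed once;
each subset's estimate is then a masked sum, evaluated in vectorized chunks
of 2048 bitmasks. The enumeration covers every non-empty subset, 2¹⁶ − 1 =
65,535 in total, with the size-16 set kept as the zero-error reference row.
The chunked path is required (and tested) to agree metric-for-metric with a
naive per-subset loop; subsets with no valid frame at all get NaN metrics and
coverage 0 and are excluded from argmins. Ties on the target metric are
broken by the lexicographically smallest sorted id tuple, which makes the
per-k argmin total and the whole search deterministic.

## Reporting

Marginal gain at k is best(k−1) − best(k) in mm; the inflection point is the
last k before the first gain below the threshold (default 1.5 mm) — the
"sufficient" sensor count, so a gain sequence whose first sub-threshold value
occurs from k to k+1 reports k. Selection frequency counts, per sensor and
target, the sizes k = 2..15 whose optimum contains the sensor.
Cross-performance tables cross the X-, Y- and XY-optimal layouts at a fixed k
with all three error metrics; diagonal dominance (each row minimizing its own
column) holds by construction and is asserted on every dataset. Spatial error
maps bin the per-frame absolute error by ground-truth CoP position on a
40 × 20 grid over the bounding box (fine enough to resolve heel/forefoot
structure, coarse enough to keep cells occupied); never-visited cells are NaN,
distinct from zero-error cells, and the display clip value is the 99th
percentile of the error distribution.

## Problem sizes and determinism

The bundled experiments use 10–20 steps per foot (two feet pooled ≈ 2,000
stance frames for the full sweep), matching the per-subject step counts of
steady-state walking trials; a full 65,535-subset sweep at that size runs in
well under a minute. Every stochastic component is seeded; the pipeline
manifest hashes all artifacts, and identical configuration yields identical
hashes.

## Known limitations

- The layout is a plausible fixture; conclusions about specific anatomical
  sites transfer to real hardware only with the true geometry.
- The generator's zone-level pulse model cannot produce pathological or
  highly asymmetric pressure patterns, and the optimization minimizes the
  stance-averaged error, under-weighting brief transients such as heel
  strike.
- The roll-over criterion replaces an unspecified peak-detection procedure
  with the bounded-regression rule above.
- Only the barycentric estimator is considered; regression or learned CoP
  estimators are out of scope.
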