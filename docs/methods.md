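# Methods

## Problem setting and model

`mosquitrack` is a tracking-by-detection pipeline. The input is a list of
anonymous per-frame centroid detections of small flying/resting insects in
a fixed camera view (640×512 px at 60 fps by default); the output is a set
of identity-consistent trajectories, one text file per individual, plus an
evaluation report against ground truth when ground truth exists.

The method assumes:

* detections are centroids with sub-pixel noise but no identity or
  appearance information;
* between consecutive frames an individual moves at most a few body
  lengths (gating is meaningful);
* misses are transient and spatially structured (background clutter,
  reflections), so trajectories are recoverable by interpolation;
* motion is smooth at the frame rate, so a cubic through the detected
  points is a good local model of the flight path.

## Data association

At each frame the open tracks and the frame's detections are matched
one-to-one by minimising the total Euclidean displacement (Hungarian
algorithm via `scipy.optimize.linear_sum_assignment`). A (track,
detection) pair is *admissible* only if

1. the displacement from the track's last position is within
   `gating_radius_px` (default 50 px — several body lengths per frame;
   a per-axis Chebyshev variant is available via `LinkParams.metric`), and
2. the direction-continuity gate passes (below).

Inadmissible pairs are excluded by a large padding constant, so the solve
first maximises the number of admissible matches and then minimises their
summed distance; with well-separated individuals this reduces to plain
nearest-neighbour linking, and the global optimum removes any dependence
on the order in which tracks are examined. Exact-cost ties are broken
toward the lexicographically smallest (track id, detection index) pairing
by an infinitesimal perturbation (1e-9 of the gating radius, far below any
genuine cost difference), which makes the assignment fully deterministic.

Unmatched detections open new tracks immediately (every individual is
tracked from its first appearance; there is no birth-confirmation window).
A track unmatched for more than `max_coast_frames` consecutive frames
(default 30, i.e. 0.5 s at 60 fps) is closed.

### Direction continuity

A candidate extension must not reverse the track's motion: the angle
between the mean heading over the last `direction_window` (default 3)
detected displacements and the heading to the candidate must be at most
`max_turn_deg` (default 120° — these insects turn sharply, so the gate
only rejects near-reversals).

The gate is skipped whenever a heading would be meaningless:

* the track has fewer than `direction_window` detected points;
* the track's recent mean speed is below
  `resting_speed_px_per_frame` (a resting, jittering individual);
* the candidate step itself is below that speed (slowing or stopping is
  always an allowed continuation).

`resting_speed_px_per_frame` defaults to **3 px/frame**, roughly three
times a typical centroid-localisation noise scale. This matters: with
1 px detection noise, a genuinely motionless individual shows apparent
frame-to-frame speeds around 1–2 px/frame, and a hard direction gate keyed
to a 1 px/frame threshold misclassifies roughly a third of resting frames
as "moving with a random heading", shredding resting tracks into
interleaved fragments that endpoint merging cannot repair (their frame
ranges overlap). Treating every sub-3 px displacement as
heading-uninformative eliminates that failure mode while leaving the gate
active for genuine flight.

### Fragment merging

Prolonged misses fragment a trajectory into several track records. Two
fragments are joined when fragment B starts 1–`max_frame_gap` frames
(default 60) after fragment A ends and the endpoint distance is at most
`max_join_distance_px` (default 50). Joins are applied greedily, smallest
endpoint distance first (ties toward smaller ids); the merged track keeps
the earlier id; overlapping frame ranges are never merged; no point is
duplicated or lost.

## Gap filling

Within each track, every missing integer frame between the first and last
*detected* frames is filled. x(frame) and y(frame) are interpolated
independently (no arc-length parameterisation — the simplest model
consistent with per-axis track files). The interpolant is the classical
natural cubic spline fitted to **all** detected points of the track:
piecewise cubics, C² at interior knots, zero second derivative at the two
end knots. The interior second derivatives solve a tridiagonal system
(`scipy.linalg.solve_banded`); with two knots the spline degenerates to
the straight line. Natural end conditions are the standard default when
the boundary derivative is unknown; clamped conditions are out of scope.

Gaps longer than `max_spline_gap` frames (default 30 ≙ 0.5 s) are filled
by linear interpolation between the bracketing detections instead: across
wide holes a cubic can overshoot by large factors, and a straight segment
is the safer prior. Filled points carry provenance `interpolated`;
detected points are never altered; no extrapolation is performed outside
the detected range. Filling is idempotent.

Measured on noise-free simulated cruises (turn smoothness 0.98, speed
2–4 px/frame), a 10-frame hold-out is recovered to ≤ 3 px RMS by the
spline; error grows with gap length and with the flight's speed
variability, which is what motivates the linear fallback.

## Evaluation metric

Per frame, the tracker error is d_f = √((p_f−x_f)² + (q_f−y_f)²).
Per individual: mean distance m₁ over defined frames, sample SD of the
d_f, and tolerance accuracy = 100 × (frames with |Δx| < tol and
|Δy| < tol) / (all ground-truth frames). Both inequalities are strict and
missing estimates count as inaccurate, so interpolation can only raise
accuracy by supplying estimates where none existed. Per scene: the
frame-pooled mean distance (per-individual means are also reported), the
(nᵢ′−1)-weighted pooled SD of the per-frame distances — the classical
pooled-variance formula, chosen as the standard reading of a "weighted
average of standard deviations" — and two unweighted accuracy means, one
over flying individuals and one over all individuals. Resting individuals
are scored by exactly the same rule.

Percentages are displayed at two decimals with half-up rounding. In the
bundled benchmark accuracy tables used by `scripts/acceptance.py`, the
third scenario's overall mean is taken over its 26 scored individuals
(25 resting at 100 % plus one flying at 95.58 %), the composition that
reproduces its published summary value exactly.

Estimated tracks are put in correspondence with ground-truth individuals
by a one-to-one assignment maximising the number of shared frames with
error below the tolerance (mean error as tie-break). This scoring
correspondence is evaluation plumbing, not part of the tracker.

## Synthetic scenes

The generator emulates a laboratory flight cage viewed by a fixed camera:

* **Fliers** follow a correlated random walk: per frame the heading turns
  by a wrapped-Gaussian angle whose concentration is `turn_smoothness`
  (the circular autocorrelation of heading; default 0.95 ≈ 18° RMS turn
  per frame), speed is drawn uniformly from `speed_range_px_per_frame`
  (default 1–6 px/frame), and trajectories reflect specularly off the
  walls. Two knobs, both interpretable; no claim of kinematic realism
  beyond "smooth but wandering". Real flight-speed and turn statistics
  for this setting are not published, so these defaults are conventions.
* **Resters** sit at anchors rejection-sampled to pairwise separation
  ≥ 10 px, with per-frame Gaussian jitter (default 0.1 px).
* **Observation model**: each true position yields a detection with
  isotropic Gaussian noise (`noise_sigma_px`, default 0.5; the benchmark
  experiments use 1.0) unless it falls inside a clutter rectangle and an
  independent Bernoulli draw with that rectangle's dropout probability
  deletes it. Dropout is position-triggered, not uniform, because misses
  in real footage cluster at specific scene structures.
* **Rendering** (optional): 8-bit grayscale frames, uniform background
  with an anti-aliased dark disc per individual, so the reference
  detector's intensity-weighted centroids reproduce the requested
  sub-pixel positions to ≤ 0.5 px.

One integer seed drives everything; per-individual streams are spawned
deterministically from it, so identical scene specifications give
bit-identical tracks, detections and frames.

What the generator does **not** model — and hence what passing tests do
not demonstrate about real videos: occlusions with merged detector masks,
perspective and 3-D motion projected to 2-D, pose- and wing-driven
centroid wander, non-stationary lighting, detector confidence landscapes,
and take-off/landing transitions between resting and flight.

## Numerical and degenerate-input choices

* Frames are 1-based everywhere; coordinates are image-convention
  (x along width, y along height, origin top-left), sub-pixel floats.
* Track text files round-trip exactly (`repr` precision, `\n` newlines,
  UTF-8); CSV readers use round-trip float parsing.
* Spline fitting demands strictly increasing knot times; evaluation
  outside the knot range raises rather than extrapolates.
* Metrics raise on empty denominators (no defined distances) instead of
  returning NaN; pairing raises on disjoint frame ranges.
* The blob detector uses 8-connected components (4-connectivity fragments
  diagonal blobs) with an area band of [3, 400] px² at 640×512, and
  merges overlapping blobs into one detection — the documented occlusion
  failure mode, handled (or not) downstream.

## Known limitations

* **Crossings**: when a flier passes directly over another individual,
  frame-to-frame geometry cannot distinguish the correct from the crossed
  assignment, and identities can swap. The association cost, gates and
  merging reduce but cannot eliminate this; high-angle crossing repair is
  out of scope (in practice it needs appearance features or manual
  correction, which the per-frame track files are designed to make easy).
* A temporal-median background absorbs perfectly static individuals, so
  the reference detector only sees resters against a known (e.g.
  rendered) background or after they move.
* The direction gate is a heuristic with two thresholds; it trades a
  small fragmentation rate (repaired by merging) for protection against
  reversals.

## Problem sizes used in the test and acceptance runs

Benchmark scenes are 540 frames (9 s at 60 fps) with 5 individuals
(2 flying); the gap-recovery experiment uses 20 replicates of that scene
with σ = 1 px noise and one 120×120 px dropout rectangle at p = 0.8; the
association oracle comparison uses 500 random instances of up to 6 tracks
and 6 detections; the spline oracle comparison uses 100 random knot sets
of 3–14 knots. The full test suite runs in well under a minute.
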