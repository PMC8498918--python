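# Methods

This note documents the models implemented in `ringpose`, the assumptions
behind them, the defaults and why they were chosen, what the synthetic
generators do and do not emulate, and the numerical choices that matter when
comparing against other software.

## Camera model

Each camera is a pinhole with one radial distortion coefficient and 8 free
parameters: axis-angle rotation `r ∈ ℝ³` (radians), translation `t ∈ ℝ³`
(world units), focal length `f` (pixels, shared between axes), and `k1`
(dimensionless). Skew is zero and the principal point is fixed at the image
center. This deliberate reduction from the full 5-parameter intrinsics /
3-parameter distortion model trades a little expressiveness for much more
robust calibration from hand-held board videos, where the higher-order terms
are weakly constrained.

Projection composes: extrinsics `p_cam = R p + t`; perspective divide;
radial distortion `x' = x (1 + k1 r²)` applied **in normalized camera
coordinates**; then `u = f x' + c`. Working in normalized coordinates keeps
`k1` independent of the focal length; software that applies distortion in
pixel coordinates will report a `k1` differing by a factor of `f²`, so
coefficients are not directly comparable across conventions. Points at or
behind the camera plane (`z ≤ 1e-9`) are reported missing rather than
wrapped through the projection. `undistort` inverts the distortion by
fixed-point iteration (≤ 20 iterations, `|k1| r² ≲ 0.3·0.25` converges
comfortably; non-convergent points are flagged missing with a warning).

Image convention: origin at the top-left pixel center, x right, y down.

## Calibration

**Initialization.** Intrinsics come from the closed-form single-focal
reduction of the standard planar-homography constraints: each board
homography `H` (estimated by normalized DLT from ≥ 4 corners) yields two
linear constraints on `1/f²`; one candidate solution is taken per
well-conditioned constraint and the median over all views is used, which
tolerates outlier-contaminated frames. If the candidates do not concentrate
(interquartile range > 5× the median — the signature of fronto-parallel-only
views, which carry no perspective information about `f`), the focal falls
back to a field-of-view prior (`f` = image width, ≈ 53° horizontal FOV) with
a warning; bundle adjustment recovers from this in practice. `k1` starts at
zero.

Extrinsics propagate over a greedy camera graph: pairs are visited in
decreasing order of co-detected board frames, an edge is added whenever it
joins two unconnected cameras, and calibration is possible iff the result is
a spanning tree. The root camera (lexicographically first, a deterministic
choice) defines the world frame; each neighbor's pose is the relative board
pose composed over shared frames. Relative transforms are averaged with a
geometric median over **sign-aligned quaternions** plus translations —
rotation-vector medians were found to fail catastrophically for ~180°
relative rotations (opposite cameras on a ring), where the rotation-vector
representation flips sign under small perturbations.

**Bundle adjustment** jointly refines all camera parameters and free 3D
corner positions (one per frame × corner, matching the loss above) by sparse
Trust-Region-Reflective least squares with 2-point finite differences and an
explicit Jacobian sparsity pattern; losses `linear`, `huber`, `soft_l1`
(scale default 10 px) are supported. The optimizer never increases its own
robustified loss. A minimum of 10 observations per free parameter is
required before an adjustment runs.

**Iterative bundle adjustment** (default) repeats the adjustment 12 times
with an inlier threshold decaying geometrically from 15 px to 1 px,
selecting observations below the threshold within a random subsample of at
most 100 frames per iteration (seeded; the subsample bounds per-iteration
cost on long recordings). Iterations whose selection falls below the
observation minimum keep the previous iterate. Afterwards all points are
re-triangulated with the refined rig — linearly, falling back per point to
the exhaustive-pair consensus search when the linear solution reprojects
worse than 5 px — and the reported summary covers all observations.

**Gauge.** A multi-camera rig is identifiable only up to a global
similarity transform. The world frame is fixed to the root camera and the
metric scale is anchored to the board: after adjustment, the rig is rescaled
so the median reconstructed spacing of horizontally adjacent corners equals
the known square size. All quality comparisons against ground truth align
rigs with a Umeyama similarity fit first.

## 2D filters

*Median*: per joint and coordinate, a centered running median (default
window 7 frames); points deviating more than `offset_threshold` (default
20 px, Euclidean) are removed; removed and pre-existing gaps up to one
window length are re-filled by cubic-spline interpolation (never
extrapolated past the series ends), and interpolated points carry score 0 so
downstream stages can distinguish them from observations.

*Viterbi*: per joint, an HMM whose states at frame `t` are the frame's
candidate detections — deduplicated within 7 px, keeping the
highest-scoring member — augmented with candidates carried from up to
`max_gap` (default 5) previous frames at score × `2^-gap`. Emission weight
is the (adjusted) score; transition weight is the isotropic Gaussian
density of the displacement with `sigma` (default 10 px). The returned path
is the exact argmax of the product of these weights (verified against
exhaustive enumeration); carryover selections are emitted as missing since
the joint was not observed in those frames, and the path restarts after
frames with no states at all. The transition density is kept untruncated:
trellis widths here (≤ top-20 candidates plus carryovers) make the exact
dense computation cheap, and exactness is one of the tested invariants.

*Autoencoder*: a single-hidden-layer tanh MLP (hidden width = number of
joints, Adam optimizer, squared-error loss against the true visibility
indicators, 500 epochs — the loss/epochs are our choices; the architecture
and optimizer are fixed) trained on synthetic score vectors: per frame each
joint is visible with probability 0.8, 10% of frames instead occlude a
contiguous joint block (our visibility prior — real occlusions are
spatially structured), scores drawn from N(1, 0.3) for visible and N(0, 0.3)
for occluded joints clipped to [0, 1], and 5% of scores flipped
(`x → 1 − x`). Applying the filter rewrites scores with the MLP output
(clipped to [0, 1]) and drops keypoints whose corrected score falls below
0.5 (our default). A note on what this filter can and cannot do: since half
of all visible scores are exactly 1.0 under the clipped-normal model, an
occluded joint scoring ≳ 0.9 is statistically indistinguishable from a
visible one even for the Bayes-optimal predictor; the filter's value lies in
suppressing moderately scored spurious detections and exploiting
cross-joint occlusion structure.

## Triangulation

*Linear*: observations are undistorted into normalized coordinates, each
camera contributes two DLT rows built from its normalized projection matrix
`[R | t]`, and the homogeneous solution is the last right singular vector.
Fewer than two observing cameras → missing.

*RANSAC*: every pair of observing cameras is triangulated and the point
minimizing the printed two-view reprojection objective is kept — an
exhaustive consensus search (camera counts are small) that exactly excludes
a corrupted view when at least two views agree.

*Regularized*: all `p_{j,t}` and one `d_l` per limb are optimized jointly.
The residual vector concatenates (i) per-observation reprojection residuals
passed through a component-wise sqrt-ρ robustifier (`soft_l1` default, scale
10 px — only this term is robustified; the temporal term stays quadratic as
specified by the model), (ii) `√α_time ·` order-k finite differences of the
positions (k = 2 by default: velocity smoothing distorts band-limited
dynamics more than acceleration smoothing at equal noise suppression), and
(iii) `√α_limb · w_l (‖p_{j1,t} − p_{j2,t}‖ − d_l)/d_l`, the
length-normalized limb residuals, with `w_l = 0.5` for limbs marked flexible
(tarsi, shoulders). The temporal scale is
`γ = N / Σ ‖p_{j,t} − p_{j,t−1}‖` over the linear initialization — the
reciprocal mean displacement, which makes `β_time` unitless (an
initialization moving 0.5 units/frame gives γ = 2). `d_l` starts at the
median limb length of the initialization; gaps in the initialization are
linearly interpolated only to seed the optimizer. After optimization,
points reprojecting worse than 20 px are masked, as are joints never
observed in the window. Recordings longer than 500 frames are processed in
500-frame chunks overlapping by 50, blended linearly — memory stays linear
in recording length; chunk size is configurable.

`smooth_series` isolates the temporal term for 1D signals (quadratic
problem, solved directly by a sparse linear system) and is what the
synthetic reconstruction evaluation uses.

## Joint angles

Flexion at joint `j` of a triplet `(i, j, k)` is
`arccos(û_{ji} · û_{jk})` in degrees, with unit vectors and the dot product
clamped to [−1, 1]. (The unnormalized form is not bounded to arccos's
domain; normalization is required for the formula to be well defined.)

For full chain angles, each joint along a chain gets a frame: z along the
distal segment, x = the proximal direction (toward the body) orthogonalized
against z, y = z × x; the first joint takes its x reference from a
user-supplied body frame (built from three reference keypoints or a fixed
world frame). Relative rotations between consecutive frames are decomposed
as intrinsic Euler {z, y, x} = (rotation, flexion, abduction). Because the
frame construction guarantees the middle Euler angle lies in [0°, 180°]
(where generic solvers restrict it to ±90°), the decomposition selects the
branch with |abduction| ≤ 90° and reports flexion = 180° − (middle angle),
which makes chain flexion *identical* to the three-point flexion above.

Observability: with segment-built frames, the x axis of every interior
frame is fixed by the geometry, so the Euler x component (abduction) is
structurally zero — from 3D positions alone, a joint's rotation cannot be
separated from the next joint's abduction. The implementation follows the
standard resolution: rotation is reported for all but the most distal
joint, the abduction slot is reported for the most proximal one, and the
forward-kinematics round trip (exact to < 1e-6°) covers the observable
angles (rotation + flexion). Frames with near-parallel segments, or flexion
within 0.1° of 0°/180° (gimbal lock), report rotation/abduction as missing.

Derivatives are one-frame forward differences × frame rate, with circular
unwrapping for rotation/abduction kinds. Feature matrices concatenate
`window` samples of every angle and its derivative (fly default: 32-sample
windows, stride 8 → 18 angles × 2 × 32 = 1152 dims; human: 24-sample
windows → 288), standardized per column; zero-variance columns are centered
only, with a warning. Step phase band-passes one angle with a zero-phase
first-order Butterworth (3–60 Hz default) and takes the analytic-signal
phase, wrapped to [−π, π).

## Synthetic scenes

The simulator provides the study conditions for every test: a ring of
`n` cameras (default 6, 832 × 632 px, focal 600 px, `k1 = −0.02`, 15°
elevation) aimed at the origin; a board moved by low-pass-filtered noise in
pose space (cutoff 0.05 cycles/sample, rotation scale 0.5 rad, translation
scale 0.12 × rig radius — chosen so most frames keep the full board visible
in several cameras); band-limited unit-variance 1D trajectories (30 series
of 500 samples, cutoff 0.12 cycles/sample) corrupted by additive noise and
10% missing samples (noise default 0.3 × signal SD — the corruption model
leaves the noise amplitude open, so it is an explicit parameter); rigid
articulated walkers with sinusoidal gait angles (2 Hz, flexion 120° ± 25°)
whose limb lengths are constant to machine precision; and detection
corruption with Gaussian jitter, teleporting outliers, missing entries, and
spurious lower-scored duplicate candidates.

What the generators deliberately do **not** emulate: correlated errors
across cameras (a detector failing the same way in two views), confidence
scores correlated with error magnitude, rolling-shutter or lens effects
beyond one radial term, non-rigid soft tissue, and appearance-driven
detector failure modes. Tests passing on these scenes therefore validate
the geometry, optimization, and filtering logic — not the upstream
detector, and not robustness to view-correlated failures, which no
multi-view consistency method can repair.

## Benchmarks

`scripts/acceptance.py` (and `tests/test_acceptance.py`) recompute, from
scratch at every run: (1) the mean reprojection error after iterative
bundle adjustment on a 6-camera / 300-frame / 0.5 px-noise board scene;
(2–3) the 90th-percentile inter-corner length error (µm) and corner-triplet
angle error (degrees) of a miniature board (2 × 2 mm pattern, 0.5 mm
squares, 9 tracked corners, 200 poses, 1 px noise, working distance ≈ 4 mm
so the board spans ≈ 300 px) triangulated linearly through a rig the
package calibrated itself. Problem sizes (300 calibration frames, 200
evaluation poses, 100-frame subsamples per adjustment iteration) keep a
full run within a few minutes on one CPU while leaving the statistics
stable across seeds. Angle triplets whose true vertex angles fall below 1°
are excluded as collinear (their angles are unstable by construction, and
the reference protocol likewise uses non-collinear triplets only).

## Known limitations

- Distortion inversion assumes moderate `|k1| r²`; fisheye-grade distortion
  is out of scope.
- The camera graph uses board co-visibility only; no animal-keypoint-based
  calibration refinement is implemented.
- The regularized optimizer is a local method: with pathological
  initializations (e.g. most joints missing for long stretches) it can
  converge to smooth but wrong trajectories, which is why wholly
  unobserved joints are masked rather than hallucinated.
- Gauge fixing relies on the board's square size; without scale anchoring,
  lengths are only defined up to a global factor.
- The behavioral embedding itself (UMAP or similar) is downstream of this
  package; only the feature construction is provided.
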