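# Methods

This note records the model behind each pipeline stage, the parameter
choices that matter, what the synthetic generator does and does not
emulate, and the numerical decisions taken where the design was open.

## Imaging model and coordinate conventions

Frames are 8-bit grayscale, light background (~200) with dark fish.
Coordinates are 0-based, `x` = column, `y` = row, pixel centers at integer
positions.  Angles are degrees counter-clockwise from +x; a fitted ellipse
orientation lives in [0, 180) (a second-derivative fit cannot distinguish
head from tail), and the motion direction disambiguates it during
tracking.

## Head detection

**Scale-space response.**  The determinant of the Gaussian Hessian,
normalized as `s⁴ (L_xx L_yy − L_xy²)`, is compared across a geometric
scale grid `s_i = s_min·1.26^i` spanning `[w_min/4, w_max/1.5]` (so heads
of width 16–24 px — the configured band — produce in-range extrema: a
solid disc of radius r peaks at `s = r/√2`).  The `s⁴` factor is the
standard γ = 1 normalization; it is what makes the disc relation and the
grid bounds consistent.  Derivative kernels are truncated at 3σ; because a
truncated derivative kernel has a small nonzero DC gain, the image mean is
removed before convolution so a constant image yields an exactly zero
response.  Dark-blob polarity is enforced by requiring `det H > 0` and
`L_xx + L_yy > 0` (an intensity minimum curves upward in both directions);
the reported `doh_value` is negated so retained extrema are minimum-like.

**Sub-grid refinement.**  Discrete 26-neighborhood extrema are refined by
a second-order Taylor step in (x, y, log s), offsets clamped to half a
grid step.  On rendered Gaussian spots (σ = 3…10) this recovers the
center to ≲ 0.1 px and the scale to ≲ 2% of a dense fine-grid search.
Extrema within `2s` of the border are discarded.

**Ellipse from the Hessian.**  With eigenvalues |λ₁| ≥ |λ₂| and
`ratio = |λ₁|/|λ₂|`, the half-axes are `√2·s·ratio^{±1/2}` along the
eigenvectors (major axis = weak-curvature direction).  The exponent was
calibrated on rendered solid ellipses of head-like aspect (~1.6), where it
recovers both axes to ~5% and the orientation to ~1°; the geometric-mean
radius `√2·s` is exact for a disc.  A gentler exponent (¼) preserves the
same geometric mean but reproduces only ~60% of the true anisotropy on
these shapes.

**Constraints.**  (i) Width: the configured `[w_min, w_max]` band is the
*physical* head-width range; the estimate is compared against the band
expanded by `width_margin` = 15%, covering the estimator's measured error
(+5% on isolated ellipses, about −10% on heads with an attached body,
whose darkness inflates the curvature ratio).  (ii) Contrast: mean gray of
the elliptical annulus between 1× and 2× the axes minus mean gray inside,
over 255, clamped to [0, 1]; effective iff ≥ k = 0.03.  (iii) Angle:
within one segmented fish region, candidates with headings (mod 180°)
closer than 30° are duplicate detections of one head and only the
highest-contrast one survives; at ≥ 30° they are treated as two occluding
fish and both are kept.  Otsu segmentation (exhaustive between-class
variance maximization, smallest-t tie-break, foreground = pixels ≤ t)
uses 8-connected components with a minimum area of `π w_min²/8` px² to
drop speckle while keeping a lone head.

Localization on rendered fish is accurate to ~1.5 px on average (max
~2.3 px): the attached body darkens the rear of the head blob and drags
the extremum slightly backward.  This is well under half a head width and
irrelevant for gating; coarse-to-fine relocalization at smaller scales was
tried and rejected (noise-dominated).

## Tracking

**Kalman filter.**  Constant-velocity model, Δt = 1 frame;
`Q = q·diag(¼, ¼, 1, 1)` with q = 1 px², `R = r·I` with r = 1 px²,
`P₀ = 10·I` — standard near-constant-velocity defaults for 30 fps
footage where fish move a few px per frame.  The gate is adaptive:
3σ of predicted positional uncertainty plus one head length.

**Matching region.**  A two-phase piecewise-constant (morphological
Chan-Vese) active contour, initialized from the detected ellipse, runs for
a fixed 20 iterations on a local window of radius 1.1× the head length
(from an ellipse init it converges in ~15–20 sweeps; a tight budget also
keeps the region from leaking along the body; smoothing weight 1).  The
outer endpoint is the farthest contour point within ±15° of the heading;
when no motion-resolved heading is available the head front is taken as
the direction in which the outline extends *less* far (the tail side runs
long) — without this the region can silently flip onto the tail.  The
cutting line through the ellipse center perpendicular to the alignment
line bounds the head-side region; its features are the cutting-line
width, the pixel area and a 256-bin gray histogram smoothed with a σ = 2
gray-level Gaussian (a few hundred pixels spread over 256 bins is
sampling-noise dominated otherwise).

**Cascade matching.**  Width (|Δw| ≤ τ_w = 5 px), then area of the
symmetric difference after rigidly mapping one region's alignment line
onto the other's (≤ τ_a = 50 px²), then histogram-intersection distance
(≤ τ_g = 0.15), early exit on failure.  The warp uses subpixel bilinear
interpolation and the statistic is minimized over a ±1 px jitter of the
endpoint: nearest-pixel warping of a ~300 px² region produces ~60 px² of
pure quantization difference, which would swamp τ_a while measuring
nothing about shape.  Identical regions still score exactly 0.  The
combined score is the mean of the three threshold-normalized statistics.

**Association.**  Per track, candidates come from the Kalman gate; only
if none passes the cascade is the quarter-circle compensation window
(radius = head length, ±45° about the heading) searched.  Passing pairs
are accepted globally, greedily by ascending score, one-to-one.  A track
that has been coasting adds 0.02 per consecutive miss to its scores: its
cached appearance is stale, and on a near-tie the freshly observed track
must win, otherwise a coasting track and its replacement alternate
stealing one fish's detection and neither ever closes.

## Lifecycle and linking

A missed frame associates a virtual observation (the prediction) and
marks the state ineffective; T1 = 10 consecutive misses close the track
as incomplete, with the end tag at the last *observed* state (the coasted
tail is dropped — those positions were never measured).  Tracks born
after frame 0 carry a start tag.  Fragments link when
`0 < st − et < T2 = 30`, `‖sp − ep‖ < D = 80` (both strict, matching the
prose reading "later than" / "less than"), and the endpoint regions pass
the cascade; among passing pairs, linking is greedy by score, one-to-one
per side, iterated to a fixed point.  Incomplete tracks stay eligible for
the rest of the video — T2 bounds the fragment gap, not when linking
runs.  Gaps are filled by linear interpolation and flagged
`interpolated = 1`.  Tracks shorter than 5 frames ("a few frames") with
no link partner are pruned as detection noise.

## Evaluation

A detection is a true positive iff its center lies within half the mean
ground-truth head length of an unmatched truth head, matched greedily by
distance, one-to-one.  OR = occlusions/(fish·frames) and
ODR = detected-occluded/occlusions; these reconstructed forms reproduce
all three published occlusion-ratio values exactly from their printed
counts (125/5000, 640/10000, 3040/20000).  Trajectory association assigns
each output trajectory to its minimum-mean-distance truth among those it
temporally overlaps; with no per-truth capacity this per-fragment optimum
is the global optimum, verified against exhaustive enumeration on small
instances.  TCF and TFF follow from the association as the mean covered
fraction and mean fragment count.  Detection wall-clock time is logged
but never asserted — it is hardware, not method.

## Synthetic generator

The generator emulates the laboratory conditions the tracker targets:
a square arena (default 1024 px standing in for a 30×30 cm tank; fish are
sized in pixels to the 16–24 px head-width band rather than physical cm),
light background with Gaussian sensor noise (σ = 5), static dark bottom
speckle, optional drifting particles; each fish a solid dark head ellipse
(width drawn from [16, 24] px, aspect 1.6) with a tapering tail of ~3.2
head widths whose bend oscillates at 1.5–3 Hz; overlaps composite by the
darkest-pixel rule and a 1 px blur stands in for optical softness.

Kinematics: angular velocity is mean-reverting with Gaussian kicks (decay
0.25, kick σ = 3°/frame), tuned so per-frame heading change stays within
±45° for ≥ 99% of frames at defaults — the empirical statistic the
compensation window is built on; speed is an Ornstein-Uhlenbeck cruise
(3 ± 0.8 px/frame) with burst-glide events (probability 0.01/frame, gain
3, multiplicative decay 0.85); walls reflect specularly.  Two optional
social terms exist for benchmark construction: repulsive steering within
`separation_radius`, and a hard minimum pairwise distance that projects
violating pairs apart ("giving way").  At 115 px the hard distance
exceeds the largest head-center-to-tail-tip reach plus a head radius, so
body masks can never touch another head: such scenes are occlusion-free
by construction, which is how the no-occlusion benchmark variant is
defined.  Occlusion flags are computed from the rendered per-fish masks
(occluded = any other body pixel inside my head mask; head_visible =
≥ 50% of head pixels uncovered).

What the generator does **not** emulate: hydrodynamics, 3-D posture and
depth-dependent blur, photorealistic texture, schooling interaction
rules, illumination drift, and reflections at the tank walls.  Passing
tests therefore demonstrate the pipeline's behavior under the stated
geometric and photometric model, not performance on any particular real
footage.

## Problem sizes and determinism

The end-to-end benchmark used by the tests and the acceptance script is a
10-fish, 300-frame school in a 512 px arena with repulsive steering
(radius 150 px) — the low-density regime; the no-occlusion variant adds
the 115 px hard distance.  All randomness flows from one explicit seed
through named substreams (motion, rendering per frame, speckle), so
identical seeds give bit-identical frames and truth, and the whole
pipeline is deterministic given frames and config.

## Known limitations

- The width estimator reads ~10% low on heads with bodies attached; the
  detection band absorbs this via its 15% margin, but per-detection width
  values should not be treated as unbiased morphometry.
- Localization carries a ~1–2 px backward bias (body darkness).
- Heavy, repeated head-on-head occlusion (dense schools) fragments tracks
  faster than linking can repair once gaps exceed T2; identity recovery
  across such gaps is out of scope.
- The association stage assumes fish appearance is stable frame-to-frame;
  strong illumination flicker would need the thresholds re-tuned.
- Nearest-neighbor and probabilistic data association baselines are not
  implemented; the association interface accepts a custom scorer.
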