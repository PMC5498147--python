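# Methods

## Tracking model

The tracker treats specimen motion between acquisitions as a lateral
translation.  For each specimen the maximum-intensity projection of the
acquired z-stack is cropped to a centered square window of side
`floor(roi_fraction · min(height, width))` pixels (default fraction ⅓).
The window is centered, not tip-anchored, because the control loop keeps
the specimen near the frame centre.  Three variants of the window — raw,
mean-filtered, median-filtered (both 3×3 by default, borders by edge
replication) — are each cross-correlated against the corresponding variant
of the previous time point.  Correlation is *direct*: the mean is
subtracted from both images and the full linear correlation surface is
evaluated (via FFT; a brute-force double loop over all lags is the test
oracle at small sizes, agreeing to 1e−6 relative tolerance).  No amplitude
normalization is applied.  Ties at the peak are broken toward the smaller
shift magnitude, then non-negative dx, then non-negative dy.  The
component-wise median of the three variant shifts is the per-step shift Δ
(pixels).  Subpixel refinement (parabolic interpolation of the peak and
its four neighbors) is available but off by default — the shift feeds a
stage prediction, which is quantized anyway.

The cumulative displacement is updated as δ(t) = δ(t−1) + Δ·pixel_size and
the next position list is P(T(n+1)) = P(T(n)) + δ.  Because each frame is
acquired *after* the stage applied the previous prediction, Δ is the
residual prediction error and the update is a constant-velocity predictor
with correction: for a specimen moving at constant velocity v, δ converges
to v·interval and the residual Δ is exactly zero from the third time point
on (in integer mode, when v·interval is a whole number of pixels), with
the tip's offset from frame centre bounded by the one uncompensated first
interval.  δ(0) = (0, 0): the first interval is always uncompensated.

Δ is measured in image pixels; δ and P are stage µm.  The conversion is a
pixel-size multiplication plus an axis map (per-axis sign, optional x/y
swap) because the stage-axis orientation relative to the camera is
hardware-dependent; the default maps image col → stage +x, row → +y.

A safety limit bounds the per-step stage move: if |δ(t)| (Euclidean norm,
inclusive comparison) exceeds `max_step_um`, that specimen is stopped with
`stop_reason=safety_limit` and keeps its last position; the others
continue.  A blank (zero-variance) window stops the specimen with
`stop_reason=zero_variance` rather than guessing a shift.  The position
list and track log are persisted after every time point, so a crashed
session leaves a usable partial record.

### Operating envelope

With window W µm and per-interval displacement d µm, steady-state tracking
is exact for d well below W/2 and the first (uncompensated) interval is
fully recovered for d ≲ W/2.  Near the recommended limit (300 µm/h at
30-min intervals against a 213 µm window, d = 150 µm > W/2) the first
interval is only partially recovered: the loop still locks onto the
specimen's rate and never loses it from the field of view, but tracking
may settle a constant one-to-two-hundred µm behind the tip.  Unnormalized
direct correlation is the reason: its peak scales with overlap area, so a
shift comparable to the window size competes against full-overlap partial
matches.  This matches the practical guidance of keeping the per-interval
displacement within the tracking window with margin.

## Rotation recomputation

The chamber-rotation centre is calibrated by imaging a small drilled hole:
the image is thresholded at its inter-modal (Otsu) level, exactly one
connected bright region is required, and its intensity centroid is mapped
to stage coordinates.  Positions are then remapped as P′ = C + R(θ)(P−C).
Angle sign: positive = clockwise as seen in the displayed image; with
rows increasing downward this is the matrix [[cos, −sin], [sin, cos]] in
(x, y) stage coordinates.  The transform is an exact isometry (tested to
1e−9); the simulated stage adds configurable Gaussian repositioning error
(default σ = 5 µm in the scene layer, 0–1 µm in most tests) so
re-acquisition robustness is exercised.

## Kinetics

Growth rate per interval is the chord length between consecutive recorded
positions divided by the elapsed time, timestamped at the interval
midpoint; intervals touching a stopped record are excluded, and no
smoothing is applied by default (an optional centered moving average is
provided).  Light-phase annotation evaluates the schedule at the midpoint,
half-open intervals [start, end).  Because the stage follows with a
one-interval delay, the rate at a phase switch reflects the previous
phase; per-phase summaries in the acceptance computation therefore use the
median, which one polluted interval per switch cannot move.  The root-tip
angle is measured from the organizing-centre→tip vector against the
gravity axis (+y, down), clockwise positive, range (−180°, 180°] — the
same sign convention as the rotation module, so a −90° chamber rotation
adds +90° to a root's angle.  The upper/lower intensity ratio sums the
stack over z and averages two congruent rectangles mirrored across an
oriented axis line ("upper" = left of the oriented axis).

## Synthetic worlds

The simulated microscope renders continuous-coordinate worlds at any stage
window, pixel size and time, then adds per-plane defocus blur (Gaussian σ
growing linearly with plane index), Gaussian noise and salt-and-pepper
impulses (at the image's own dynamic range).  All randomness derives from
a single seed via stable hashes of the arguments; equal seeds give
bit-identical stacks.

The **root world** emulates a membrane-marker root tip: a tube (radius
40 µm) whose apex advances along the integral of a piecewise-constant
speed profile (supports day/night modulation, 50–300 µm/h), with a bright
dense root cap at the apex, three staggered cell files across the radius,
cross-walls whose spacing follows the real axial organisation — short
(~10–20 µm) meristem cells lengthening ~30% per cell through the
elongation zone (capped at 4×) — and per-wall/per-cell brightness
variation.  These choices are not cosmetic: the aperiodic, chirped wall
pattern and the distinctive cap are what give the correlation surface a
unique peak, as they do in real images.  The rendered root translates
*rigidly* with the tip (every wall at a fixed distance behind the apex).
A real root elongates distributively — material far behind the elongation
zone is stationary — so the rigid model overstates how much of the frame
moves; it was chosen because it makes the tracking ground truth exact.
Passing tests therefore demonstrate correct closed-loop behaviour for
translating content, not performance under intra-frame shear.  Cell
divisions are bookkept separately in arc-length coordinates: every cell
splits at its midpoint each `division_period_h` (synchronized rounds), and
the wall ledger (position, creation time) drives membrane-generation
counts: after k synchronized rounds each pair of adjacent first-generation
walls encloses 2^k − 1 new walls.  Gravitropic bending relaxes the growth
direction toward gravity at `curvature_deg_per_h`, with the body rendered
straight along the instantaneous direction — a geometric approximation;
ground-truth tip positions remain exact.

The **cluster world** (zebrafish-like migrating cell group) renders
overlapping soft-disk cells with zero-mean offsets about a moving centroid
plus small deterministic sinusoidal jitter; the rendered centroid tracks
the path within one cell radius.

## Problem sizes

Tests and the acceptance script keep world-scale quantities at study
values (640 µm field of view, ⅓ tracking window = 213 µm, 50–300 µm/h,
20–30-min intervals) but sample at 2 µm/px over 320 px frames with 3
z-planes — the package's chosen desk-scale geometry; the full-resolution
geometry (1400 px at 0.457 µm/px, 14 z-planes) is the simulator's default
for production-style runs.  The closed-loop acceptance run covers 73 time
points (24 h at 20 min); shift-recovery suites use 200 random textures
(64×64) and 50 salt-and-pepper trials (160×160).

## Numerical choices and limitations

* Correlation on float64; surfaces compared to the brute-force oracle at
  1e−6 relative tolerance; rotation identities at 1e−9 µm.
* Exact peak ties (binary-equal correlation values) are resolved by the
  documented magnitude/sign rule; FFT rounding makes true ties rare.
* Integer-mode tracking quantizes δ to whole pixels per step; rate
  estimates inherit a ±pixel_size/interval quantization (6 µm/h at
  2 µm/px and 20-min intervals), visible as 252 vs 250 µm/h in the
  day/night recovery.
* CSV round trips use full-precision float repr and round-trip parsing;
  TIFF outputs embed no timestamps, so identical inputs give
  byte-identical files.
* Tracking in z is out of scope (specimens are assumed confined near the
  focal plane); rotation-invariant or feature-based registration is out
  of scope (the shift model is pure translation).
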