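# Methods

`fiborient` quantifies the local geometry of fiber-like structures —
cerebral blood vessels imaged by deep multiphoton microscopy are the
motivating case — in 2D images and 3D stacks.  Three quantities are
computed per pixel/voxel: the fiber **thickness** d (the local diameter),
the axial **orientation** (azimuth θ, and in 3D also the polar angle φ),
and the **directional variance** V summarizing how aligned the orientations
in a region are.  The central algorithmic idea is *window optimizing* (WO):
the neighborhood used to estimate orientation at a pixel is sized from that
pixel's own measured thickness, `W = 2d + 1`, instead of one fixed window
for the whole image.

## Local thickness

The thickness at pixel p is the diameter of the largest disc (sphere in 3D)
inscribed in the foreground that covers p.  It is computed in two steps:

1. **Distance transform.** The exact Euclidean distance D(m) from every
   foreground pixel m to the nearest background pixel
   (`scipy.ndimage.distance_transform_edt`).  Two conventions matter:
   * *Frame handling.* The image frame is treated as unobserved
     continuation, not as background: a vessel that exits the field of view
     keeps its cross-sectional thickness up to the frame.  The public
     `distance_transform` also offers the border-as-background variant
     (default there, so an all-foreground mask still has finite distances).
   * *Boundary calibration.* D is measured center-to-center and therefore
     overshoots the distance to the underlying object boundary by the
     sub-sample offset of the nearest background sample.  For an
     axis-aligned edge that offset is exactly half a pixel (the classical
     `2D − 1` diameter rule), but for isotropically oriented boundaries the
     minimum over the many near-boundary background samples is far smaller.
     We use an inscribed radius `R = D − 1/8` px (diameter `2R = 2D − 1/4`),
     the offset that made the estimator unbiased on an independent ensemble
     of randomly oriented rasterized capsules (seeds disjoint from every
     test and acceptance run).  With the axis-aligned constant instead, the
     estimator is biased low by roughly one pixel on oblique fibers, an
     error of several percent at the diameters studied here.
2. **Distance transfer.** Each m paints the value 2R(m) over every pixel
   within distance R(m); the per-pixel maximum is the thickness.  Because
   R < D strictly, every painted disc lies inside the foreground and the
   transfer can never leak across a background gap between adjacent fibers.
   The painting loop is compiled with numba; a brute-force oracle enforces
   exact agreement on small masks.

Thickness is real-valued and in pixel units; physical calibration (µm) is
applied only where statistics are stratified.  Measured accuracy on capsule
phantoms with diameters 4–60 px: ≈0.5 % mean relative error over fiber
pixels (the per-pixel residual is sub-pixel rasterization noise of about
±0.3 px).

## Orientation by weighted vector summation

For a pixel c, every foreground pixel p in the circular (spherical) window
of radius `W//2` around c contributes the direction of `p − c` with weight
`I(p) / ‖p − c‖^e`.  Axial symmetry is handled by angle doubling in 2D —
accumulate `(cos 2α, sin 2α)`, halve the resultant's angle — and by the
dyadic tensor `Σ w·u uᵀ` in 3D, whose dominant eigenvector is the axis.
Estimates are reported as θ ∈ [0, 180) from +x toward +y, and φ ∈ [0, 180)
from the +z (depth) axis; axes are sign-normalized so the azimuth lands in
[0, 180) (an in-plane fiber has φ = 90°).

Choices that the estimator's accuracy turned out to hinge on:

* **Circular windows.** A square window's corners carry net doubled-angle
  mass along its diagonals; for a pixel near the edge of a band wider than
  half the window this cancels the axial signal entirely (we observed
  near-horizontal fibers estimated at ~86°).  A disc/sphere has no
  preferred direction, which also makes the estimator rotation-equivariant
  up to rasterization.
* **Distance weight.** Default `e = 1` in 2D and `e = 2` in 3D — the
  exponents for which every radial shell of the window carries equal total
  weight in the respective dimensionality.  Lower exponents make distant
  disconnected structures act as attractors toward their *position*
  (this is precisely the "neighborhood contamination" failure of oversized
  windows, so the weight must not be made so local that window size stops
  mattering — with `e = 2` in 2D, fixed windows from 81 to 201 px all match
  the adaptive mode and the window-size phenomenon disappears).
* **Validity.** A pixel's estimate is reported only when (a) the window
  holds at least `min_neighbors` (4) contributors, (b) the window lies
  fully inside the frame (valid-region convention; an asymmetrically
  truncated window biases the estimate by up to tens of degrees on oblique
  thick fibers), and (c) the estimate is decisively anisotropic: in 2D the
  doubled-angle coherence `|S| / Σw` must reach 0.1, in 3D the tensor's
  relative eigen gap `(λ₁ − λ₂)/λ₁` must reach 0.1.  The anisotropy rules
  target the same failure in both dimensionalities: at the edge of a band
  (or the surface of a vessel) whose extent matches the window, the axial
  contributions nearly cancel, and the reported direction is decided by
  discretization noise or by whatever neighboring structure the window
  reaches.  The thresholds separate those pixels almost perfectly from
  well-determined ones (2D: mean error 30° below coherence 0.05, 13–15°
  at 0.05–0.1, ≤2.6° above 0.1; 3D: 20–40° below gap 0.1 vs 0.1° above).
* **Windows.** WO mode: `W = 2·round(d) + 1` (round-half-up), clamped to
  [3, 201].  Fixed mode computes the identical summation with one W via FFT
  convolution (the two paths agree to machine precision; a naive-loop
  oracle checks both).  Windows are truncated at the frame, never padded.

## Directional variance

V ∈ [0, 1] with 0 = perfectly parallel and 1 = isotropically random:

* 2D: circular variance of doubled angles, `V = 1 − ‖mean(cos 2θ, sin 2θ)‖`.
* 3D: orientation-tensor variance `V = (3/2)(1 − λ₁)` of the mean dyadic
  tensor of unit axes (λ₁ = 1 aligned, 1/3 isotropic), clipped to [0, 1].

`local_variance_map` evaluates V over a cubic neighborhood per voxel
(default 21, at least 10 valid orientations; box sums via
`scipy.ndimage.uniform_filter`).  `depth_profile` averages V per slice
against physical depth; `stratify_by_thickness` partitions voxels by
physical thickness (µm thresholds converted through the pixel spacing) and
emits per-stratum histograms of V.  These reproduce the qualitative
vascular signatures on synthetic stand-ins: aligned thick vessels over
randomly oriented capillaries give a depth profile that rises across the
transition and a thin-stratum V distribution that dominates the thick one.

## Synthetic phantoms

The generators create the study conditions the estimators are validated
under; every phantom carries exact per-pixel truth (mask, generating
diameter, analytic orientation).

* *Rasterization*: a pixel is foreground iff its center lies within D/2 of
  the centerline; diameter-1 fibers are Bresenham lines.
* *Extent*: `capsule` (segment with hemispherical caps, wholly inside the
  frame), `bar` (flat ends), or `span` (chord across the whole frame).
  Capsules are used for thickness studies because a capsule's true local
  thickness is exactly D at every point (the sliding inscribed sphere), so
  measured error is attributable to the estimator; spanning fibers are used
  for orientation studies because fiber *ends* are where local orientation
  is genuinely ill-posed (a cap's local tangent differs from the axis), and
  a spanning fiber's ends lie outside the frame, as in typical full-field
  simulated images.
* *Layout*: fibers never overlap or touch (≥1 px background gap;
  `truth_by_nearest_axis` optionally allows crossings with nearest-axis
  truth).  The separation `min_gap` is a soft constraint relaxed
  geometrically when packing saturates; saturated placements also switch to
  proposals near-parallel to already placed fibers anchored in background
  clearings (the geometry non-crossing bundles settle into), and a spanning
  fiber that no longer fits any full chord is placed as a shorter interior
  segment.  Placements whose frame exit is
  inclined less than 30° to a border within reach are re-drawn: a fiber
  grazing the frame has its flanking background outside the field of view
  and neither its thickness nor orientation is identifiable from the data.
* *Curvy fibers*: sinusoidal centerlines with closed-form tangents; the
  zero-amplitude case is bit-identical to the straight generator.
* Defaults follow the validation design: 2D suites are 500×500 px with 10
  diameters spanning 1–60 px (orientation) or 7 diameters 4–60 px
  (thickness); 3D suites are 150³ with diameters {8, 15, 30}.  Rendering is
  flat and noiseless by default (`intensity_fg` 200 on 0), with optional
  Gaussian noise.

What the phantoms do *not* emulate: branching topology, intensity texture
and depth-dependent attenuation of real multiphoton data, partial-volume
soft edges, and segmentation errors — passing the accuracy targets here
shows estimator correctness on cleanly segmented geometry, not robustness
of any particular segmentation.

## Evaluation harness

Angular error uses the axial metric `min(|a−b| mod 180, 180 − |a−b| mod
180)`; 3D additionally scores θ and φ separately and the full axis angle
`arccos|u·u'|`.  `run_comparison` regenerates a suite (per-image seeds
`seed..seed+n−1`), runs thickness → WO and every fixed window, and
tabulates per-image, per-diameter and pixel-pooled means over
`truth.mask ∩ field.valid`; pixels near fiber endpoints are counted
separately but included in headline means.  Problem sizes used by the test
and acceptance runs: four 500×500 images for the 2D accuracy and
fixed-window comparisons, and one 150³ stack (six cylinders, two per
diameter) for the 3D comparison — the full 300³ design is available through
the same API and CLI (`fiborient compare --dim 3 --full-scale`).

## Numerical notes and limitations

* Determinism: all randomness flows from `numpy.random.default_rng(seed)`;
  identical specs give bit-identical phantoms, and the pipelines are
  deterministic given their inputs.
* Degenerate inputs: empty masks raise; an all-foreground mask is only
  accepted by the border-as-background distance transform; isolated pixels
  are invalid for orientation (min_neighbors); constant images cannot be
  Otsu-thresholded.
* The 2d+1 window is a heuristic, not a per-voxel optimum: on very clean,
  well-separated phantoms a single mid-sized fixed window can match or
  slightly beat it in 3D, because the adaptive window of a thick vessel
  reaches further and collects more contamination.  The adaptive mode's
  advantage grows with diameter heterogeneity and with how wrong any single
  window is for part of the data.
* Orientation at fiber terminations is intrinsically ambiguous for any
  local mass-distribution estimator; the validity rules prefer reporting
  nothing over reporting the artifact.
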