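# fiborient

Pixel/voxel-wise quantification of fibrous structures in 2D images and 3D
stacks: local **thickness**, axial **orientation**, and **directional
variance** (alignment).  The package targets vascular imagery — e.g. deep
multiphoton stacks of cerebral blood vessels, where capillaries a few
microns wide coexist with vessels an order of magnitude thicker — but
applies to any fiber-like binary or grayscale data (collagen, axons,
filaments).

## The method

Local orientation estimators need a neighborhood (window) scaled to the
structure: too small a window undersamples a thick vessel's interior, too
large a window mixes in neighboring fibers.  With heterogeneous calibers no
single window fits.  The **window-optimizing (WO)** approach measures the
thickness first and sizes the window per pixel:

1. **Thickness.** From the binary mask, the Euclidean distance transform
   D(m) to the background is converted to an inscribed radius
   R(m) = D(m) − 1/8 px, and each pixel's thickness is
   `d(p) = max { 2·R(m) : ‖p − m‖ ≤ R(m) }` — the diameter of the largest
   inscribed disc/sphere covering p.
2. **Orientation.** At every foreground pixel c, direction vectors to the
   foreground pixels p in the disc (2D) or ball (3D) of diameter
   `W = 2·d(c) + 1` are summed with weight `I(p)/‖p − c‖^e`.  Axial symmetry
   (θ ≡ θ + 180°) is respected by angle doubling in 2D and by the dyadic
   tensor `Σ w·u uᵀ` in 3D, whose dominant eigenvector gives the axis.
   Angles: azimuth θ ∈ [0°, 180°) from +x, polar φ ∈ [0°, 180°) from the
   depth axis (φ = 90° means in-plane).
3. **Alignment.** Directional variance V ∈ [0, 1]
   (`1 − ‖mean(cos 2θ, sin 2θ)‖` in 2D, `(3/2)(1 − λ₁)` of the mean axis
   tensor in 3D) is 0 for parallel fibers and 1 for isotropically random
   ones, and is summarized per neighborhood, per depth slice, and per
   thickness stratum.

A synthetic-phantom module generates fiber images with exact per-pixel
ground truth (orientation, thickness, mask), and an evaluation harness
scores the adaptive mode against fixed windows.  See `docs/methods.md` for
the full model description and design rationale.

## A worked example

```python
import numpy as np
from fiborient import (PhantomSpec, generate_straight_fibers_2d,
                       local_thickness, orient2d, error_map)

spec = PhantomSpec(dims=(300, 300), diameters=(6.0, 40.0),
                   fiber_extent="span", min_gap=10.0, seed=4)
image, truth = generate_straight_fibers_2d(spec)

thickness = local_thickness(truth.mask)          # per-pixel diameter, px
field = orient2d(image, truth.mask, thickness)   # adaptive 2d+1 windows
err = error_map(field, truth, "theta2d").values

print(f"thin fiber thickness : {thickness.values[truth.thickness == 6].mean():.2f} px")
print(f"thick fiber thickness: {thickness.values[truth.thickness == 40].mean():.2f} px")
print(f"mean angular error   : {np.nanmean(err):.2f} deg")
```

prints

```
thin fiber thickness : 5.80 px
thick fiber thickness: 39.95 px
mean angular error   : 0.71 deg
```

i.e. the 6 px and 40 px fibers are both recovered to sub-pixel thickness
accuracy, and the per-pixel orientations agree with the generating angles
to a fraction of a degree — with one adaptive pass instead of one window
per caliber.  The `examples/` directory holds short scripts for each
capability (thickness maps, 2D/3D orientation, alignment statistics, the
full adaptive-vs-fixed comparison), and the `fiborient` command line
exposes the same pipelines for TIFF inputs (`fiborient orient --help`).

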