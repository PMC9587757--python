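"""Adaptive (window-optimizing) vs fixed-window 2D orientation.

Generates one 300x300 image with fibers of very different calibers, then
estimates the per-pixel orientation twice: with the window sized per pixel
as 2d+1 from the local thickness d, and with one fixed 21 px window.  The
printed lines give the mean angular error against exact ground truth and
how many fiber pixels each mode could answer for — no single window suits
both a 6 px and a 40 px fiber.
"""

import numpy as np

from fiborient import (
    OrientationParams,
    PhantomSpec,
    error_map,
    generate_straight_fibers_2d,
    local_thickness,
    orient2d,
)

spec = PhantomSpec(
    dims=(300, 300), diameters=(6.0, 40.0), fiber_extent="span",
    min_gap=10.0, seed=4,
)
image, truth = generate_straight_fibers_2d(spec)
thickness = local_thickness(truth.mask)

adaptive = orient2d(image, truth.mask, thickness)
fixed = orient2d(image, truth.mask, None,
                 OrientationParams(mode="fixed", fixed_window=21))

for name, field in [("adaptive 2d+1", adaptive), ("fixed 21 px", fixed)]:
    err = error_map(field, truth, "theta2d").values
    n_valid = int(np.isfinite(err).sum())
    print(f"{name:13s}: mean error {np.nanmean(err):5.2f} deg, "
          f"{n_valid}/{int(truth.mask.sum())} fiber pixels answered")
# The 21 px window cannot resolve the 40 px fiber: inside it the window sees
# a featureless disc, the doubled-angle resultant loses coherence, and the
# estimator abstains on most of the image.  The adaptive window answers
# nearly everywhere at the same accuracy.
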