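"""Compact end-to-end oracle checks shared by the acceptance suite."""

import numpy as np


def brute_thickness_small() -> bool:
    """local_thickness matches the brute-force covering-disc maximum."""
    from fiborient import local_thickness
    from test_thickness import brute_force_thickness

    g = np.random.default_rng(42)
    mask = np.zeros((40, 40), bool)
    yy, xx = np.mgrid[0:40, 0:40]
    for _ in range(3):
        cy, cx, r = g.integers(6, 34), g.integers(6, 34), g.integers(2, 8)
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    return np.allclose(local_thickness(mask).values, brute_force_thickness(mask))


def naive_orientation_small() -> bool:
    """Windowed summation matches the naive double loop on a small mask."""
    from fiborient import ImageStack, OrientationParams, orient2d
    from fiborient.thickness import ThicknessMap
    from test_orientation import naive_orient2d

    g = np.random.default_rng(43)
    mask = g.random((24, 24)) < 0.5
    weight = np.where(mask, g.uniform(50, 250, (24, 24)), 0.0)
    wins = np.where(mask, g.choice([3, 7, 11], (24, 24)), 0)
    thick = ThicknessMap(np.where(mask, (wins - 1) / 2.0, 0.0))
    fld = orient2d(ImageStack(weight), mask, thick,
                   OrientationParams(min_neighbors=1, require_full_window=False))
    ref_theta, _ = naive_orient2d(mask, weight, wins, 1.0)
    sel = fld.valid
    d = np.abs(fld.theta[sel] - ref_theta[sel])
    return bool(np.nanmax(np.minimum(d, 180 - d)) < 1e-6)
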