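import numpy as np
import pytest

from fiborient.phantoms import PhantomTruth, _capsule_pixels_2d


def make_band_2d(width, angle_deg, shape=(200, 200), half_len=1000.0, flat_ends=False):
    """Single straight fiber band with exact truth (helper, not a fixture)."""
    H, W = shape
    rr, cc, tang, dists, end_dist = _capsule_pixels_2d(
        angle_deg, (H - 1) / 2, (W - 1) / 2, half_len, 0.0, 150.0, 0.0,
        width, shape, flat_ends=flat_ends,
    )
    mask = np.zeros(shape, bool)
    mask[rr, cc] = True
    theta = np.full(shape, np.nan, np.float32)
    theta[rr, cc] = tang
    thick = np.zeros(shape, np.float32)
    thick[rr, cc] = width
    near_end = np.zeros(shape, bool)
    near_end[rr, cc] = end_dist < width
    return PhantomTruth(mask=mask, thickness=thick, theta=theta, near_end=near_end)


def make_cylinder_3d(diameter, axis, shape=(64, 64, 64), half_len=1000.0):
    """Single cylinder along a given (x, y, z) axis through the center."""
    Z, H, W = shape
    u = np.asarray(axis, float)
    u = u / np.linalg.norm(u)
    zz, yy, xx = np.meshgrid(
        np.arange(Z, dtype=float), np.arange(H, dtype=float), np.arange(W, dtype=float),
        indexing="ij",
    )
    wx, wy, wz = xx - (W - 1) / 2, yy - (H - 1) / 2, zz - (Z - 1) / 2
    proj = np.clip(wx * u[0] + wy * u[1] + wz * u[2], -half_len, half_len)
    d2 = (wx - proj * u[0]) ** 2 + (wy - proj * u[1]) ** 2 + (wz - proj * u[2]) ** 2
    return d2 <= (diameter / 2.0) ** 2


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
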