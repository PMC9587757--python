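"""Pixel/voxel-wise axial orientation by weighted orientation vector summation.

For every foreground pixel c, direction vectors to the foreground pixels p in
a circular (2D) or spherical (3D) window centered on c are summed with weight
``I(p) / |p-c|^e`` (intensity over distance, e = 1 by default).  Axial
symmetry (an orientation and its opposite are the same) is respected by
doubling angles in 2D and by accumulating dyadic tensors ``u u^T`` in 3D,
where the dominant eigenvector gives the orientation.

Two windowing modes are provided:

``wo`` (window optimizing)
    the window is chosen per pixel as ``2 d + 1`` where d is the local fiber
    thickness — small windows on capillaries, large windows on thick vessels,
    which avoids both undersampling and neighborhood contamination.
``fixed``
    one window size for the whole image, the conventional approach the
    adaptive mode is compared against.

Angles are reported in degrees: azimuth theta in [0, 180) measured from +x
toward +y, and (3D) polar angle phi in [0, 180) measured from the +z (depth)
axis, both in [0, 180).  Windows are
truncated at image borders rather than padded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .imgio import BinaryMask, ImageStack
from .thickness import ThicknessMap

WINDOW_MIN = 3
WINDOW_MAX = 201


@dataclass
class OrientationParams:
    """Estimator configuration.

    ``mode`` is ``"wo"`` (adaptive window 2d+1) or ``"fixed"``;
    ``fixed_window`` (odd, >= 3) is required in fixed mode.
    ``weight_distance_exponent`` is the e in the 1/r^e distance weight
    (default: 1 in 2D, 2 in 3D — the exponents that weight every radial
    shell of the window equally in each dimensionality);
    ``use_intensity_weight`` multiplies each contribution by the neighbor's
    raw intensity.  Pixels with fewer than ``min_neighbors`` contributors are
    marked invalid, as are (with ``require_full_window``, the default)
    pixels whose window extends beyond the image frame — there the truncated
    geometry, not the fibers, would dominate the estimate.  2D pixels whose
    doubled-angle coherence |S| / sum(w) falls below ``coherence_tol`` are
    invalid: at the edge of a band wider than half the window the axial
    contributions cancel and the resultant is decided by noise or by
    whatever neighboring structure the window reaches.  In 3D, voxels
    whose orientation tensor has a relative gap (l1-l2)/l1 below
    ``eig_tie_tol`` are invalid: near the surface of a thick vessel the
    axial and circumferential directions are almost equally represented in
    the window, and below this anisotropy the eigenvector is decided by
    discretization noise rather than structure.
    """

    mode: str = "wo"
    fixed_window: int | None = None
    weight_distance_exponent: float | None = None
    use_intensity_weight: bool = True
    min_neighbors: int = 4
    require_full_window: bool = True
    window_min: int = WINDOW_MIN
    window_max: int = WINDOW_MAX
    eig_tie_tol: float = 0.1
    coherence_tol: float = 0.1

    def __post_init__(self):
        if self.mode not in ("wo", "fixed"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "fixed":
            if self.fixed_window is None:
                raise ValueError("fixed mode requires fixed_window")
            if self.fixed_window < 3 or self.fixed_window % 2 == 0:
                raise ValueError("fixed_window must be odd and >= 3")
        if self.weight_distance_exponent is not None and self.weight_distance_exponent < 0:
            raise ValueError("weight_distance_exponent must be >= 0")
        if self.min_neighbors < 1:
            raise ValueError("min_neighbors must be >= 1")


@dataclass
class OrientationField:
    """Per-pixel axial orientation with validity and window provenance.

    ``theta`` (and ``phi`` for 3D) are degrees in [0, 180), NaN where
    invalid; ``window_used`` is the odd window size per pixel (0 off-mask).
    """

    theta: np.ndarray
    phi: np.ndarray | None = None
    window_used: np.ndarray | None = None

    @property
    def valid(self) -> np.ndarray:
        v = np.isfinite(self.theta)
        if self.phi is not None:
            v &= np.isfinite(self.phi)
        return v


def window_size(d, window_min: int = WINDOW_MIN, window_max: int = WINDOW_MAX):
    """Adaptive window size 2*round(d) + 1 for thickness d, clamped odd.

    Rounding is half-up; the result is clamped to [window_min, window_max].
    Accepts scalars or arrays; d must be > 0.
    """
    arr = np.asarray(d, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("thickness must be > 0")
    w = 2 * np.floor(arr + 0.5).astype(np.int64) + 1
    w = np.clip(w, window_min, window_max)
    return int(w) if np.isscalar(d) else w


def _weights(img, mask, params):
    if params.use_intensity_weight:
        w = np.asarray(img.values if isinstance(img, ImageStack) else img, dtype=np.float64)
        w = np.where(mask, np.maximum(w, 0.0), 0.0)
    else:
        w = mask.astype(np.float64)
    return w


def _window_map(mask, thick, params):
    wins = np.zeros(mask.shape, np.int64)
    if params.mode == "fixed":
        wins[mask] = params.fixed_window
    else:
        t = thick.values if isinstance(thick, ThicknessMap) else np.asarray(thick)
        wins[mask] = window_size(t[mask], params.window_min, params.window_max)
    return wins


def _full_window_fits(wins: np.ndarray) -> np.ndarray:
    """True where the per-pixel window lies entirely inside the frame."""
    r = wins // 2
    fits = np.ones(wins.shape, bool)
    for ax, n in enumerate(wins.shape):
        idx = np.arange(n)
        margin = np.minimum(idx, n - 1 - idx)
        sh = [1] * wins.ndim
        sh[ax] = n
        fits &= margin.reshape(sh) >= r
    return fits


def _fft_kernels_2d(w, exponent):
    r = w // 2
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1].astype(float)
    r2 = dx * dx + dy * dy
    inside = (r2 > 0) & (r2 <= r * r)  # circular window
    with np.errstate(divide="ignore"):
        base = np.where(inside, r2 ** (-0.5 * exponent - 1.0), 0.0)
    kc = (dx * dx - dy * dy) * base
    ks = 2.0 * dx * dy * base
    kw = r2 * base  # plain 1/r^e weight, for the coherence normalizer
    kn = inside.astype(float)
    return kc, ks, kw, kn


def _fft_kernels_3d(w, exponent):
    r = w // 2
    dz, dy, dx = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1].astype(float)
    r2 = dx * dx + dy * dy + dz * dz
    inside = (r2 > 0) & (r2 <= r * r)  # spherical window
    with np.errstate(divide="ignore"):
        base = np.where(inside, r2 ** (-0.5 * exponent - 1.0), 0.0)
    comps = [dx * dx * base, dy * dy * base, dz * dz * base,
             dx * dy * base, dx * dz * base, dy * dz * base]
    kn = inside.astype(float)
    return comps, kn


def orient2d(img, mask, thick=None, params: OrientationParams | None = None) -> OrientationField:
    """2D orientation field by doubled-angle weighted vector summation.

    In ``wo`` mode ``thick`` (a :class:`ThicknessMap`) is required.  The
    doubled-angle resultant (sum of cos 2a, sin 2a contributions) is halved
    back: theta = 0.5 * atan2(S_sin, S_cos) mapped to [0, 180).
    """
    from ._kernels import orient2d_sum

    params = params or OrientationParams()
    m = mask.values if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
    if m.ndim != 2:
        raise ValueError("orient2d requires 2D inputs")
    vals = img.values if isinstance(img, ImageStack) else np.asarray(img)
    if vals.shape != m.shape:
        raise ValueError("image and mask shapes differ")
    if params.mode == "wo" and thick is None:
        raise ValueError("wo mode requires a thickness map")
    exponent = 1.0 if params.weight_distance_exponent is None else params.weight_distance_exponent
    weight = _weights(img, m, params)
    wins = _window_map(m, thick, params)

    if params.mode == "fixed":
        kc, ks, kw, kn = _fft_kernels_2d(params.fixed_window, exponent)
        sc = fftconvolve(weight, kc, mode="same")
        ss = fftconvolve(weight, ks, mode="same")
        sw = fftconvolve(weight, kw, mode="same")
        cnt = np.rint(fftconvolve(m.astype(float), kn, mode="same")).astype(np.int64)
    else:
        sc, ss, sw, cnt = orient2d_sum(m, weight, wins, exponent)

    theta = np.full(m.shape, np.nan)
    ok = m & (cnt >= params.min_neighbors)
    if params.coherence_tol > 0:
        # doubled-angle coherence in [0, 1]: the 2D analog of the 3D eigen
        # gap — below it the resultant is noise, not structure
        with np.errstate(invalid="ignore", divide="ignore"):
            coh = np.where(sw > 0, np.hypot(sc, ss) / np.where(sw > 0, sw, 1.0), 0.0)
        ok &= coh >= params.coherence_tol
    if params.require_full_window:
        ok &= _full_window_fits(wins)
    theta[ok] = (0.5 * np.degrees(np.arctan2(ss[ok], sc[ok]))) % 180.0
    wins = np.where(ok, wins, 0)
    return OrientationField(theta=theta, window_used=wins)


def _tensor_to_angles(T6, sel, tie_tol):
    """Batched eigenanalysis of the 3x3 tensors at the selected voxels."""
    n = int(sel.sum())
    M = np.empty((n, 3, 3))
    txx, tyy, tzz, txy, txz, tyz = (c[sel] for c in T6)
    M[:, 0, 0], M[:, 1, 1], M[:, 2, 2] = txx, tyy, tzz
    M[:, 0, 1] = M[:, 1, 0] = txy
    M[:, 0, 2] = M[:, 2, 0] = txz
    M[:, 1, 2] = M[:, 2, 1] = tyz
    lam, vec = np.linalg.eigh(M)  # ascending
    lam1, lam2 = lam[:, 2], lam[:, 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        gap = np.where(lam1 > 0, (lam1 - lam2) / lam1, 0.0)
    good = (lam1 > 0) & (gap >= tie_tol)
    v = vec[:, :, 2]  # (x, y, z)
    # sign canonicalization: y >= 0 (so theta lands in [0, 180)); on the
    # y ~ 0 ring, x >= 0; then z >= 0
    eps = 1e-9
    flip = (v[:, 1] < -eps) | (
        (np.abs(v[:, 1]) <= eps)
        & ((v[:, 0] < -eps) | ((np.abs(v[:, 0]) <= eps) & (v[:, 2] < 0)))
    )
    v[flip] *= -1.0
    # zero sub-epsilon components before atan2: a numerically tiny negative
    # y would otherwise wrap theta to ~180 without the matching phi flip,
    # silently changing the represented axis
    on_ring = np.abs(v[:, 1]) <= eps
    vy = np.where(on_ring, 0.0, v[:, 1])
    vx = np.where(on_ring & (np.abs(v[:, 0]) <= eps), 0.0, v[:, 0])
    theta = np.degrees(np.arctan2(vy, np.where(on_ring, np.abs(vx), vx)))
    phi = np.degrees(np.arccos(np.clip(v[:, 2], -1.0, 1.0)))
    theta[~good] = np.nan
    phi[~good] = np.nan
    return theta, phi


def orient3d(img, mask, thick=None, params: OrientationParams | None = None) -> OrientationField:
    """3D orientation field by weighted dyadic-tensor summation.

    The dominant eigenvector of the accumulated tensor gives the axis; voxels
    whose two leading eigenvalues tie within ``eig_tie_tol`` (isotropic
    neighborhoods) are invalid.
    """
    from ._kernels import orient3d_sum

    params = params or OrientationParams()
    m = mask.values if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
    if m.ndim != 3:
        raise ValueError("orient3d requires 3D inputs")
    vals = img.values if isinstance(img, ImageStack) else np.asarray(img)
    if vals.shape != m.shape:
        raise ValueError("image and mask shapes differ")
    if params.mode == "wo" and thick is None:
        raise ValueError("wo mode requires a thickness map")
    exponent = 2.0 if params.weight_distance_exponent is None else params.weight_distance_exponent
    weight = _weights(img, m, params)
    wins = _window_map(m, thick, params)

    if params.mode == "fixed":
        comps, kn = _fft_kernels_3d(params.fixed_window, exponent)
        T6 = [fftconvolve(weight, k, mode="same") for k in comps]
        cnt = np.rint(fftconvolve(m.astype(float), kn, mode="same")).astype(np.int64)
    else:
        T, cnt = orient3d_sum(m, weight, wins, exponent)
        T6 = [T[i] for i in range(6)]

    theta = np.full(m.shape, np.nan)
    phi = np.full(m.shape, np.nan)
    sel = m & (cnt >= params.min_neighbors)
    if params.require_full_window:
        sel &= _full_window_fits(wins)
    if sel.any():
        th, ph = _tensor_to_angles(T6, sel, params.eig_tie_tol)
        theta[sel] = th
        phi[sel] = ph
    ok = np.isfinite(theta)
    wins = np.where(ok, wins, 0)
    return OrientationField(theta=theta, phi=phi, window_used=wins)


def orient(img, mask, thick=None, params: OrientationParams | None = None) -> OrientationField:
    """Dimensionality-dispatching front end for orient2d / orient3d."""
    m = mask.values if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
    fn = orient2d if m.ndim == 2 else orient3d
    return fn(img, mask, thick, params)
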