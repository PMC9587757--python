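"""Synthetic fiber phantoms with exact per-pixel ground truth.

These generators emulate the simulation studies used to validate the
window-optimizing orientation method: 2D images (500x500 px) of straight or
curvy fibers with diameters spanning 1-60 px, and 3D stacks (up to 300^3
voxels) of straight cylinders with diameters 8-30 voxels.  Every phantom is
emitted together with a :class:`PhantomTruth` holding the exact orientation
and thickness at every foreground pixel, so estimator accuracy can be scored
without any external data.

Fibers are capsules: a pixel belongs to a fiber iff its center lies within
D/2 (Euclidean) of the fiber's centerline segment, which gives straight
bands / cylinders of constant width with hemispherical caps.  Capsules are
placed entirely inside the field of view.  This geometry is chosen because
its ground-truth local thickness is exactly D everywhere (every point is
covered by an inscribed disc of diameter D sliding along the centerline),
so estimator error is attributable to the estimator alone rather than to
frame truncation.  Diameter-1 fibers degenerate to 1-pixel digital
(Bresenham) lines.  Identical spec (including seed) gives bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .imgio import ImageStack

_RETRY_CAP = 4000
_FRAME_MARGIN = 2.0  # px clearance between a capsule and the frame
_LENGTH_RANGE = (0.45, 0.85)  # fiber length as a fraction of min(dims)


_GRAZE_ANGLE = 30.0  # deg: minimum inclination of a frame exit
_GRAZE_MARGIN = 2.0  # px


def _chord_endpoints(origin, direction, lows, highs):
    """Clip the line origin + t*direction to the box [lows, highs]."""
    tlo, thi = -np.inf, np.inf
    for c0, dc, lo, hi in zip(origin, direction, lows, highs):
        if abs(dc) < 1e-12:
            if not (lo <= c0 <= hi):
                return None
        else:
            t0, t1 = (lo - c0) / dc, (hi - c0) / dc
            tlo = max(tlo, min(t0, t1))
            thi = min(thi, max(t0, t1))
    if tlo > thi:
        return None
    o, d = np.asarray(origin, float), np.asarray(direction, float)
    return o + tlo * d, o + thi * d


def _grazes_frame(origin, direction, diameter, dims_xyz) -> bool:
    """True if the axis exits the field of view nearly parallel to a border.

    A fiber grazing a frame edge has background on one side outside the
    field of view, so neither its thickness nor its orientation is cleanly
    identifiable from the observed region; such degenerate placements are
    re-drawn.  Checked at both chord endpoints against every border plane
    closer than the fiber radius (plus margin).
    """
    lows = [0.0] * len(dims_xyz)
    highs = [float(n - 1) for n in dims_xyz]
    ends = _chord_endpoints(origin, direction, lows, highs)
    if ends is None:
        return True  # axis misses the frame entirely
    near = diameter / 2.0 + _GRAZE_MARGIN
    u = np.asarray(direction, float)
    u = u / np.linalg.norm(u)
    for end in ends:
        for ax, n in enumerate(dims_xyz):
            if min(end[ax], n - 1 - end[ax]) < near:
                incl = np.degrees(np.arcsin(min(abs(u[ax]), 1.0)))
                if incl < _GRAZE_ANGLE:
                    return True
    return False


class PlacementError(RuntimeError):
    """No non-overlapping placement found for a fiber within the retry cap."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic fiber phantom.

    ``dims`` is ``(H, W)`` for 2D or ``(Z, H, W)`` for 3D, in pixels/voxels.
    ``diameters`` lists fiber diameters in pixels; ``n_fibers_per_diameter``
    fibers are placed for each.  ``overlap_policy`` is ``"forbid"`` (place and
    retry so no two fibers share a pixel; a one-pixel background gap is also
    enforced so fibers never touch) or ``"truth_by_nearest_axis"`` (crossings
    allowed; contested pixels take the truth of the nearest axis).
    """

    dims: tuple[int, ...]
    diameters: tuple[float, ...]
    n_fibers_per_diameter: int = 1
    fiber_model: str = "straight"  # straight | curvy
    curvature_amplitude: float = 0.0  # px, sinusoidal displacement amplitude
    curvature_period: float = 150.0  # px
    fiber_extent: str = "capsule"  # capsule | bar | span
    min_gap: float = 1.0  # minimum background gap between fibers, px
    intensity_fg: float = 200.0
    intensity_bg: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0
    overlap_policy: str = "forbid"

    def __post_init__(self):
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "diameters", tuple(float(d) for d in self.diameters))
        if len(self.dims) not in (2, 3):
            raise ValueError("dims must have 2 or 3 entries")
        if any(d < 32 for d in self.dims):
            raise ValueError("all dims entries must be >= 32")
        if not self.diameters:
            raise ValueError("at least one diameter is required")
        if any(d <= 0 for d in self.diameters):
            raise ValueError("diameters must be positive")
        if any(d >= min(self.dims) / 2 for d in self.diameters):
            raise ValueError("diameters must be < min(dims)/2")
        if self.n_fibers_per_diameter < 1:
            raise ValueError("n_fibers_per_diameter must be >= 1")
        if self.fiber_model not in ("straight", "curvy"):
            raise ValueError(f"unknown fiber_model {self.fiber_model!r}")
        if self.curvature_amplitude < 0:
            raise ValueError("curvature_amplitude must be >= 0")
        if self.curvature_period <= 0:
            raise ValueError("curvature_period must be > 0")
        if self.intensity_fg <= 0:
            raise ValueError("intensity_fg must be positive")
        if self.intensity_bg < 0 or self.noise_sd < 0:
            raise ValueError("intensity_bg and noise_sd must be >= 0")
        if self.overlap_policy not in ("forbid", "truth_by_nearest_axis"):
            raise ValueError(f"unknown overlap_policy {self.overlap_policy!r}")
        if self.fiber_extent not in ("capsule", "bar", "span"):
            raise ValueError(f"unknown fiber_extent {self.fiber_extent!r}")
        if self.min_gap < 0:
            raise ValueError("min_gap must be >= 0")


@dataclass
class PhantomTruth:
    """Exact ground truth emitted with every phantom.

    ``theta`` and (3D) ``phi`` hold axial angles in degrees in [0, 180)
    on fiber pixels, NaN elsewhere; ``thickness`` holds the generating fiber
    diameter on fiber pixels and 0 on background; ``near_end`` flags fiber
    pixels within one diameter of their fiber's endpoint.
    """

    mask: np.ndarray
    thickness: np.ndarray
    theta: np.ndarray
    phi: np.ndarray | None = None  # 3D only; polar angle from +z
    near_end: np.ndarray | None = None

    def __post_init__(self):
        assert self.mask.dtype == bool


def _canonical_axis(u: np.ndarray) -> np.ndarray:
    """Flip a 3-vector so y >= 0; if y ~ 0, x >= 0; if x ~ 0 too, z >= 0.

    This puts the azimuth in [0, 180) while the polar angle keeps its full
    [0, 180) range — together they cover every axis exactly once.  (A
    z-first sign rule would clash with reducing the azimuth mod 180: axes
    with y < 0 would silently map to a different axis.)
    """
    eps = 1e-12
    if u[1] < -eps or (abs(u[1]) <= eps and (u[0] < -eps or (abs(u[0]) <= eps and u[2] < 0))):
        return -u
    return u


def axis_to_angles(u) -> tuple[float, float]:
    """Azimuth theta (from +x, in the xy plane) and polar phi (from +z), deg.

    The axis is sign-canonicalized first (y >= 0), so theta lands in
    [0, 180) and phi keeps its full [0, 180) range.
    """
    u = _canonical_axis(np.asarray(u, dtype=float))
    u = u / np.linalg.norm(u)
    eps = 1e-12
    uy = 0.0 if abs(u[1]) <= eps else u[1]
    ux = abs(u[0]) if (uy == 0.0 and abs(u[0]) <= eps) else u[0]
    if uy == 0.0:
        ux = abs(ux)  # on the y=0 ring theta is 0, never 180
    theta = np.degrees(np.arctan2(uy, ux))
    phi = np.degrees(np.arccos(np.clip(u[2], -1.0, 1.0)))
    return float(theta), float(phi)


def angles_to_axis(theta: float, phi: float) -> np.ndarray:
    """Unit axis (x, y, z) for azimuth theta and polar phi in degrees."""
    t, p = np.radians(theta), np.radians(phi)
    return np.array([np.sin(p) * np.cos(t), np.sin(p) * np.sin(t), np.cos(p)])


# ---------------------------------------------------------------------------
# 2D generation


def _capsule_pixels_2d(theta_deg, cy, cx, half_len, amp, period, phase, diameter, shape,
                       flat_ends=False):
    """Pixels within diameter/2 of a (possibly sinusoidal) centerline segment.

    With ``flat_ends`` the fiber is cut perpendicular to the centerline at
    both endpoints (a rectangular bar) instead of rounded with half-disc
    caps.

    The centerline is P(t) = c + t*a + amp*sin(2*pi*t/period + phase)*n for
    t in [-half_len, half_len], with a the base axis and n its normal.
    Returns (rows, cols, tangent_deg, axis_dist, end_dist): the analytic
    tangent angle of the nearest centerline point, the distance to the
    centerline, and the along-axis distance to the nearer endpoint, per
    selected pixel.  For amp == 0 this is the exact point-to-segment
    distance (a stadium/capsule).
    """
    H, W = shape
    th = np.radians(theta_deg)
    a = np.array([np.cos(th), np.sin(th)])  # (x, y)
    n = np.array([-np.sin(th), np.cos(th)])

    yy, xx = np.mgrid[0:H, 0:W]
    px = xx.ravel().astype(float)
    py = yy.ravel().astype(float)

    if amp == 0.0:
        relx, rely = px - cx, py - cy
        s = relx * a[0] + rely * a[1]
        d_perp = np.abs(relx * n[0] + rely * n[1])
        sc = np.clip(s, -half_len, half_len)
        fx, fy = cx + sc * a[0], cy + sc * a[1]
        dist = np.hypot(px - fx, py - fy)
        if flat_ends:
            sel = (np.abs(s) <= half_len) & (d_perp <= diameter / 2.0)
            dist = d_perp
        else:
            sel = dist <= diameter / 2.0
        tang = np.full(int(sel.sum()), theta_deg % 180.0)
        end_dist = half_len - np.abs(sc[sel])
        return (
            py[sel].astype(int), px[sel].astype(int), tang,
            dist[sel], end_dist,
        )

    step = 0.25
    t = np.arange(-half_len, half_len + step, step)
    disp = amp * np.sin(2 * np.pi * t / period + phase)
    sx = cx + t * a[0] + disp * n[0]
    sy = cy + t * a[1] + disp * n[1]
    tree = cKDTree(np.column_stack([sx, sy]))
    kd_dist, kd_idx = tree.query(np.column_stack([px, py]), k=1)
    near = kd_dist <= diameter / 2.0 + step
    if not near.any():
        e = np.empty(0)
        return np.empty(0, int), np.empty(0, int), e, e, e

    # refine: exact distance to the polyline segments adjacent to the nearest
    # sample, plus the foot parameter for the analytic tangent
    pxn, pyn, idx = px[near], py[near], kd_idx[near]
    best_d = np.full(pxn.shape, np.inf)
    best_t = np.zeros(pxn.shape)
    for i0, i1 in ((idx - 1, idx), (idx, idx + 1)):
        i0c = np.clip(i0, 0, len(t) - 1)
        i1c = np.clip(i1, 0, len(t) - 1)
        ax_, ay_ = sx[i0c], sy[i0c]
        bx_, by_ = sx[i1c], sy[i1c]
        vx, vy = bx_ - ax_, by_ - ay_
        vv = vx * vx + vy * vy
        s = np.where(vv > 0, ((pxn - ax_) * vx + (pyn - ay_) * vy) / np.where(vv > 0, vv, 1.0), 0.0)
        s = np.clip(s, 0.0, 1.0)
        fx, fy = ax_ + s * vx, ay_ + s * vy
        dseg = np.hypot(pxn - fx, pyn - fy)
        upd = dseg < best_d
        best_d = np.where(upd, dseg, best_d)
        best_t = np.where(upd, t[i0c] + s * (t[i1c] - t[i0c]), best_t)

    sel = best_d <= diameter / 2.0
    if flat_ends:
        sel &= np.abs(best_t) < half_len - 1e-9
    tfoot = best_t[sel]
    dx = a[0] + amp * (2 * np.pi / period) * np.cos(2 * np.pi * tfoot / period + phase) * n[0]
    dy = a[1] + amp * (2 * np.pi / period) * np.cos(2 * np.pi * tfoot / period + phase) * n[1]
    tang = np.degrees(np.arctan2(dy, dx)) % 180.0
    end_dist = half_len - np.abs(tfoot)
    return pyn[sel].astype(int), pxn[sel].astype(int), tang, best_d[sel], end_dist


def _bresenham_segment(theta_deg, cy, cx, half_len, shape):
    """Integer pixels of a 1-px digital line segment centered at (cy, cx)."""
    from skimage.draw import line as sk_line

    H, W = shape
    d = np.array([np.cos(np.radians(theta_deg)), np.sin(np.radians(theta_deg))])
    y0 = int(np.clip(round(cy - half_len * d[1]), 0, H - 1))
    x0 = int(np.clip(round(cx - half_len * d[0]), 0, W - 1))
    y1 = int(np.clip(round(cy + half_len * d[1]), 0, H - 1))
    x1 = int(np.clip(round(cx + half_len * d[0]), 0, W - 1))
    return sk_line(y0, x0, y1, x1)


def _fits_frame(endpoints, diameter, dims_xyz, extra=0.0) -> bool:
    """Capsule (both endpoints + radius + margin) inside the field of view."""
    clear = diameter / 2.0 + _FRAME_MARGIN + extra
    for e in endpoints:
        for c, n in zip(e, dims_xyz):
            if c < clear or c > n - 1 - clear:
                return False
    return True


def _render(spec: PhantomSpec, mask: np.ndarray, rng) -> ImageStack:
    img = spec.intensity_bg + (spec.intensity_fg - spec.intensity_bg) * mask.astype(np.float32)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=mask.shape).astype(np.float32)
    return ImageStack(img.astype(np.float32))


def _generate_2d(spec: PhantomSpec, amplitude: float):
    H, W = spec.dims
    rng = np.random.default_rng(spec.seed)
    mask = np.zeros((H, W), bool)
    dist2mask = np.full((H, W), np.inf)  # distance to existing fibers
    thick = np.zeros((H, W), np.float32)
    theta = np.full((H, W), np.nan, np.float32)
    near_end = np.zeros((H, W), bool)
    axis_dist = np.full((H, W), np.inf, np.float32)  # nearest-axis arbitration
    placed_angles: list[float] = []

    for D in sorted(spec.diameters, reverse=True):  # thick first eases packing
        for _ in range(spec.n_fibers_per_diameter):
            for attempt in range(_RETRY_CAP):
                th = rng.uniform(0.0, 180.0)
                cy = rng.uniform(0, H - 1)
                cx = rng.uniform(0, W - 1)
                if attempt >= _RETRY_CAP // 4 and placed_angles:
                    # saturated packing: propose near-parallel to an existing
                    # fiber (the geometry non-crossing bundles settle into)
                    # and anchor at a background pixel with enough clearance
                    th = (placed_angles[int(rng.integers(len(placed_angles)))]
                          + rng.normal(0.0, 4.0)) % 180.0
                    clear = np.argwhere(dist2mask > D / 2.0 + 2.0)
                    if len(clear):
                        cy, cx = clear[int(rng.integers(len(clear)))].astype(float)
                phase = rng.uniform(0.0, 2 * np.pi)
                if spec.fiber_extent == "span" and attempt < 3 * _RETRY_CAP // 4:
                    half_len = float(np.hypot(H, W))  # crosses the whole frame
                    a = [np.cos(np.radians(th)), np.sin(np.radians(th))]
                    if _grazes_frame((cx, cy), a, D, (W, H)):
                        continue
                elif spec.fiber_extent == "span":
                    # last resort in a saturated packing: a shorter interior
                    # segment can thread corridors no full chord fits
                    half_len = 0.35 * min(H, W)
                    a = np.array([np.cos(np.radians(th)), np.sin(np.radians(th))])
                    ends = [(cx - half_len * a[0], cy - half_len * a[1]),
                            (cx + half_len * a[0], cy + half_len * a[1])]
                    if not _fits_frame(ends, D, (W, H), extra=amplitude):
                        continue
                else:
                    half_len = 0.5 * min(H, W) * rng.uniform(*_LENGTH_RANGE)
                    a = np.array([np.cos(np.radians(th)), np.sin(np.radians(th))])
                    ends = [(cx - half_len * a[0], cy - half_len * a[1]),
                            (cx + half_len * a[0], cy + half_len * a[1])]
                    if not _fits_frame(ends, D, (W, H), extra=amplitude):
                        continue
                if D <= 1.0:
                    rr, cc = _bresenham_segment(th, cy, cx, half_len, (H, W))
                    tang = np.full(rr.shape, th % 180.0)
                    dists = np.zeros(rr.shape, np.float32)
                    ne = np.zeros(rr.shape, bool)
                else:
                    rr, cc, tang, dists, end_dist = _capsule_pixels_2d(
                        th, cy, cx, half_len, amplitude,
                        spec.curvature_period, phase, D, (H, W),
                        flat_ends=spec.fiber_extent == "bar",
                    )
                    ne = end_dist < D
                if rr.size == 0:
                    continue
                # separation is a soft constraint: relax geometrically once
                # the packing saturates, with a 1-px hard floor (no touching)
                gap_now = spec.min_gap if attempt < _RETRY_CAP // 2 else (
                    spec.min_gap / 2 if attempt < 3 * _RETRY_CAP // 4 else 1.0
                )
                if spec.overlap_policy == "forbid" and (
                    dist2mask[rr, cc] <= max(gap_now, 1.0)
                ).any():
                    continue
                win = dists < axis_dist[rr, cc]
                mask[rr, cc] = True
                dist2mask = ndi.distance_transform_edt(~mask)
                thick[rr[win], cc[win]] = D
                theta[rr[win], cc[win]] = tang[win]
                near_end[rr[win], cc[win]] = ne[win]
                axis_dist[rr[win], cc[win]] = dists[win].astype(np.float32)
                break
            else:
                raise PlacementError(
                    f"could not place a diameter-{D:g} fiber without overlap "
                    f"after {_RETRY_CAP} attempts"
                )

    truth = PhantomTruth(
        mask=mask, thickness=thick, theta=theta, near_end=near_end
    )
    return _render(spec, mask, rng), truth


def generate_straight_fibers_2d(spec: PhantomSpec):
    """Generate a 2D image of straight fiber bands with exact truth."""
    if len(spec.dims) != 2:
        raise ValueError("2D generator requires 2 dims")
    if spec.fiber_model != "straight":
        raise ValueError("spec.fiber_model must be 'straight'")
    return _generate_2d(spec, amplitude=0.0)


def generate_curvy_fibers_2d(spec: PhantomSpec):
    """Generate a 2D image of sinusoidal fibers; truth holds analytic tangents."""
    if len(spec.dims) != 2:
        raise ValueError("2D generator requires 2 dims")
    if spec.fiber_model != "curvy":
        raise ValueError("spec.fiber_model must be 'curvy'")
    return _generate_2d(spec, amplitude=spec.curvature_amplitude)


# ---------------------------------------------------------------------------
# 3D generation


def generate_fibers_3d(spec: PhantomSpec):
    """Generate a 3D stack of straight capsules at random axes with truth."""
    if len(spec.dims) != 3:
        raise ValueError("3D generator requires 3 dims")
    Z, H, W = spec.dims
    rng = np.random.default_rng(spec.seed)
    mask = np.zeros((Z, H, W), bool)
    dist2mask = np.full((Z, H, W), np.inf)
    thick = np.zeros((Z, H, W), np.float32)
    theta = np.full((Z, H, W), np.nan, np.float32)
    phi = np.full((Z, H, W), np.nan, np.float32)
    near_end = np.zeros((Z, H, W), bool)
    axis_dist = np.full((Z, H, W), np.inf, np.float32)

    zz, yy, xx = np.meshgrid(
        np.arange(Z, dtype=np.float32),
        np.arange(H, dtype=np.float32),
        np.arange(W, dtype=np.float32),
        indexing="ij",
    )

    for D in sorted(spec.diameters, reverse=True):
        for _ in range(spec.n_fibers_per_diameter):
            for attempt in range(_RETRY_CAP):
                u = rng.standard_normal(3)
                u /= np.linalg.norm(u)
                u = _canonical_axis(u)  # (x, y, z)
                th, ph = axis_to_angles(u)
                cz = rng.uniform(0, Z - 1)
                cy = rng.uniform(0, H - 1)
                cx = rng.uniform(0, W - 1)
                if spec.fiber_extent == "span":
                    half_len = float(np.sqrt(Z * Z + H * H + W * W))
                    if _grazes_frame((cx, cy, cz), u, D, (W, H, Z)):
                        continue
                else:
                    half_len = 0.5 * min(Z, H, W) * rng.uniform(*_LENGTH_RANGE)
                    ends = [
                        (cx - half_len * u[0], cy - half_len * u[1], cz - half_len * u[2]),
                        (cx + half_len * u[0], cy + half_len * u[1], cz + half_len * u[2]),
                    ]
                    if not _fits_frame(ends, D, (W, H, Z)):
                        continue
                wx, wy, wz = xx - cx, yy - cy, zz - cz
                proj_raw = wx * u[0] + wy * u[1] + wz * u[2]
                proj = np.clip(proj_raw, -half_len, half_len)
                dist2 = (
                    (wx - proj * u[0]) ** 2
                    + (wy - proj * u[1]) ** 2
                    + (wz - proj * u[2]) ** 2
                )
                cand = dist2 <= (D / 2.0) ** 2
                if spec.fiber_extent == "bar":
                    perp2 = wx * wx + wy * wy + wz * wz - proj_raw * proj_raw
                    cand = (np.abs(proj_raw) <= half_len) & (perp2 <= (D / 2.0) ** 2)
                    dist2 = np.maximum(perp2, 0.0)
                if not cand.any():
                    continue
                gap_now = spec.min_gap if attempt < _RETRY_CAP // 2 else (
                    spec.min_gap / 2 if attempt < 3 * _RETRY_CAP // 4 else 1.0
                )
                if spec.overlap_policy == "forbid" and (
                    dist2mask[cand] <= max(gap_now, 1.0)
                ).any():
                    continue
                d = np.sqrt(dist2, dtype=np.float32)
                win = cand & (d < axis_dist)
                mask |= cand
                dist2mask = ndi.distance_transform_edt(~mask)
                thick[win] = D
                theta[win] = th
                phi[win] = ph
                near_end[win] = (half_len - np.abs(proj))[win] < D
                axis_dist[win] = d[win]
                break
            else:
                raise PlacementError(
                    f"could not place a diameter-{D:g} cylinder without overlap "
                    f"after {_RETRY_CAP} attempts"
                )

    truth = PhantomTruth(
        mask=mask, thickness=thick, theta=theta, phi=phi, near_end=near_end
    )
    return _render(spec, mask, rng), truth


def generate(spec: PhantomSpec):
    """Dispatch to the straight/curvy 2D or 3D generator based on the spec."""
    if len(spec.dims) == 3:
        return generate_fibers_3d(spec)
    if spec.fiber_model == "curvy":
        return generate_curvy_fibers_2d(spec)
    return generate_straight_fibers_2d(spec)


# ---------------------------------------------------------------------------
# canonical study suites


def suite_2d_spec(seed: int = 1, curvy: bool = False) -> PhantomSpec:
    """The standard 2D accuracy suite: 500x500 px, 10 diameters spanning 1-60.

    Curvy variant uses diameters 4-60 with gentle sinusoidal centerlines.
    """
    if curvy:
        return PhantomSpec(
            dims=(500, 500),
            diameters=(4, 8, 12, 16, 24, 32, 40, 50, 60),
            fiber_model="curvy",
            curvature_amplitude=12.0,
            curvature_period=250.0,
            fiber_extent="span",
            min_gap=10.0,
            seed=seed,
        )
    return PhantomSpec(
        dims=(500, 500),
        diameters=(1, 4, 8, 12, 16, 24, 32, 40, 50, 60),
        fiber_extent="span",
        min_gap=10.0,
        seed=seed,
    )


def suite_3d_spec(seed: int = 1, dims=(150, 150, 150), n_fibers_per_diameter: int = 2) -> PhantomSpec:
    """The 3D cylinder suite with diameters 8, 15 and 30 voxels.

    The default 150^3 layout halves the linear scale of the full 300^3
    design while keeping the fibers' relative spacing (2 fibers per
    diameter, 24-voxel separation).
    """
    return PhantomSpec(
        dims=dims,
        diameters=(8, 15, 30),
        n_fibers_per_diameter=n_fibers_per_diameter,
        fiber_extent="span",
        min_gap=24.0,
        seed=seed,
    )


def thickness_suite_spec(seed: int = 1) -> PhantomSpec:
    """The thickness-accuracy suite: capsule fibers, diameters 4-60 px.

    Capsules keep the ground-truth local thickness exactly D everywhere,
    so the measured error is attributable to the estimator alone.
    """
    return PhantomSpec(
        dims=(500, 500),
        diameters=(4, 8, 16, 24, 32, 48, 60),
        fiber_extent="capsule",
        min_gap=2.0,
        seed=seed,
    )


def write_phantom(outdir, img: ImageStack, truth: PhantomTruth, spec: PhantomSpec) -> None:
    """Write image + truth TIFFs and a plain-text parameter sidecar."""
    from .imgio import write_stack

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_stack(img, outdir / "image.tif")
    write_stack(truth.thickness, outdir / "truth_thickness.tif")
    write_stack(truth.theta, outdir / "truth_theta.tif")
    if truth.phi is not None:
        write_stack(truth.phi, outdir / "truth_phi.tif")
    with open(outdir / "params.txt", "w") as fh:
        for k, v in vars(spec).items():
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            fh.write(f"{k} = {v}\n")
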