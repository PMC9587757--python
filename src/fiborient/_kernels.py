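"""Numba-compiled inner loops: thickness painting and windowed summation.

All kernels are exact (no approximation): correctness relative to the naive
per-pixel definitions is enforced by brute-force oracle tests on small
instances.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def paint_thickness_2d(radius: np.ndarray) -> np.ndarray:
    """Local thickness by disc painting.

    For every pixel m with inscribed radius R(m) > 0, paint the diameter
    2*R(m) onto every pixel within Euclidean distance R(m) of m, keeping the
    per-pixel maximum: thickness(p) = max_{m: |p-m| <= R(m)} 2 R(m).
    """
    H, W = radius.shape
    out = np.zeros((H, W), np.float64)
    for y in range(H):
        for x in range(W):
            R = radius[y, x]
            if R <= 0.0:
                continue
            val = 2.0 * R
            r = int(R)
            R2 = R * R
            for yy in range(max(0, y - r), min(H, y + r + 1)):
                dy2 = (yy - y) * (yy - y)
                for xx in range(max(0, x - r), min(W, x + r + 1)):
                    if out[yy, xx] < val and dy2 + (xx - x) * (xx - x) <= R2:
                        out[yy, xx] = val
    return out


@njit(cache=True)
def paint_thickness_3d(radius: np.ndarray) -> np.ndarray:
    """3D counterpart of :func:`paint_thickness_2d` (sphere painting)."""
    Z, H, W = radius.shape
    out = np.zeros((Z, H, W), np.float64)
    for z in range(Z):
        for y in range(H):
            for x in range(W):
                R = radius[z, y, x]
                if R <= 0.0:
                    continue
                val = 2.0 * R
                r = int(R)
                R2 = R * R
                for zz in range(max(0, z - r), min(Z, z + r + 1)):
                    dz2 = (zz - z) * (zz - z)
                    for yy in range(max(0, y - r), min(H, y + r + 1)):
                        d2 = dz2 + (yy - y) * (yy - y)
                        if d2 > R2:
                            continue
                        for xx in range(max(0, x - r), min(W, x + r + 1)):
                            if out[zz, yy, xx] < val and d2 + (xx - x) * (xx - x) <= R2:
                                out[zz, yy, xx] = val
    return out


@njit(cache=True)
def orient2d_sum(mask, weight, wins, exponent):
    """Doubled-angle weighted vector summation with per-pixel window sizes.

    For each pixel c with wins[c] > 0, sums weight(p)/|p-c|^exponent times
    (cos 2a, sin 2a) over foreground pixels p != c inside the circular
    window of radius wins[c] // 2 (the disc inscribed in the nominal square
    window; a disc has no preferred direction, so the window shape cannot
    bias the estimate), a being the direction angle of p-c.  Windows are
    truncated at image borders.  Returns the two sum components and the
    contributor count.
    """
    H, W = mask.shape
    sc = np.zeros((H, W), np.float64)
    ss = np.zeros((H, W), np.float64)
    sw = np.zeros((H, W), np.float64)
    cnt = np.zeros((H, W), np.int64)
    for y in range(H):
        for x in range(W):
            w = wins[y, x]
            if w <= 0:
                continue
            r = w // 2
            r2max = float(r * r)
            acc_c = 0.0
            acc_s = 0.0
            acc_w = 0.0
            n = 0
            for yy in range(max(0, y - r), min(H, y + r + 1)):
                dy = yy - y
                for xx in range(max(0, x - r), min(W, x + r + 1)):
                    if not mask[yy, xx]:
                        continue
                    dx = xx - x
                    r2 = float(dx * dx + dy * dy)
                    if r2 == 0.0 or r2 > r2max:
                        continue
                    # weight/r^e * (cos 2a, sin 2a); cos 2a = (dx^2-dy^2)/r^2
                    g = weight[yy, xx] * r2 ** (-0.5 * exponent - 1.0)
                    acc_c += g * (dx * dx - dy * dy)
                    acc_s += g * (2.0 * dx * dy)
                    acc_w += g * r2  # the contribution's weight I/r^e
                    n += 1
            sc[y, x] = acc_c
            ss[y, x] = acc_s
            sw[y, x] = acc_w
            cnt[y, x] = n
    return sc, ss, sw, cnt


@njit(cache=True)
def orient3d_sum(mask, weight, wins, exponent):
    """Weighted dyadic-tensor summation with per-voxel window sizes.

    Accumulates T(c) = sum_p w(p) u u^T with u = (p-c)/|p-c| over foreground
    voxels p != c inside the spherical window of radius wins // 2 (see
    :func:`orient2d_sum`), truncated at the stack borders.  Returns the six
    unique tensor components (xx, yy, zz, xy, xz, yz) and the contributor
    count.
    """
    Z, H, W = mask.shape
    T = np.zeros((6, Z, H, W), np.float64)
    cnt = np.zeros((Z, H, W), np.int64)
    for z in range(Z):
        for y in range(H):
            for x in range(W):
                w = wins[z, y, x]
                if w <= 0:
                    continue
                r = w // 2
                r2max = float(r * r)
                t0 = t1 = t2 = t3 = t4 = t5 = 0.0
                n = 0
                for zz in range(max(0, z - r), min(Z, z + r + 1)):
                    dz = zz - z
                    for yy in range(max(0, y - r), min(H, y + r + 1)):
                        dy = yy - y
                        for xx in range(max(0, x - r), min(W, x + r + 1)):
                            if not mask[zz, yy, xx]:
                                continue
                            dx = xx - x
                            r2 = float(dx * dx + dy * dy + dz * dz)
                            if r2 == 0.0 or r2 > r2max:
                                continue
                            g = weight[zz, yy, xx] * r2 ** (-0.5 * exponent - 1.0)
                            t0 += g * dx * dx
                            t1 += g * dy * dy
                            t2 += g * dz * dz
                            t3 += g * dx * dy
                            t4 += g * dx * dz
                            t5 += g * dy * dz
                            n += 1
                T[0, z, y, x] = t0
                T[1, z, y, x] = t1
                T[2, z, y, x] = t2
                T[3, z, y, x] = t3
                T[4, z, y, x] = t4
                T[5, z, y, x] = t5
                cnt[z, y, x] = n
    return T, cnt
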