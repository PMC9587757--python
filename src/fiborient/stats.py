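"""Alignment statistics for axial orientation data.

Directional variance V quantifies how spread a set of orientations is:
V = 0 for perfectly parallel fibers and V -> 1 for isotropically random ones.
In 2D it is the circular variance of doubled angles,
``V = 1 - |mean(cos 2t, sin 2t)|``; in 3D it is the normalized orientation
tensor variance ``V = (3/2) (1 - lambda_1)`` where lambda_1 is the largest
eigenvalue of the mean dyadic tensor of the unit axes (lambda_1 = 1 aligned,
1/3 isotropic).

Built on these are local variance maps (per-voxel V over a cubic
neighborhood), depth profiles (per-slice mean V against physical depth) and
thickness-stratified variance distributions — the read-outs used to describe
how well vessels of different calibers are aligned at different depths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .phantoms import angles_to_axis  # noqa: F401  (re-exported convenience)


class InsufficientDataError(ValueError):
    """Fewer than two finite orientations supplied."""


def directional_variance_2d(thetas) -> float:
    """Circular variance of axial 2D angles (degrees); in [0, 1]."""
    t = np.asarray(thetas, dtype=float).ravel()
    t = t[np.isfinite(t)]
    if t.size < 2:
        raise InsufficientDataError("need at least 2 finite angles")
    tr = np.radians(2.0 * t)
    R = np.hypot(np.cos(tr).mean(), np.sin(tr).mean())
    return float(np.clip(1.0 - R, 0.0, 1.0))


def _axes_from_pairs(pairs) -> np.ndarray:
    a = np.asarray(pairs, dtype=float)
    if a.ndim != 2 or a.shape[1] != 2:
        raise ValueError("expected an (n, 2) array of (theta, phi) degrees")
    ok = np.isfinite(a).all(axis=1)
    a = a[ok]
    t, p = np.radians(a[:, 0]), np.radians(a[:, 1])
    return np.column_stack([np.sin(p) * np.cos(t), np.sin(p) * np.sin(t), np.cos(p)])


def directional_variance_3d(axes) -> float:
    """Orientation-tensor variance of 3D axes given as (theta, phi) degrees.

    V = (3/2) * (1 - lambda_1) of the mean dyadic tensor, clipped to [0, 1].
    """
    u = _axes_from_pairs(axes)
    if u.shape[0] < 2:
        raise InsufficientDataError("need at least 2 finite axis pairs")
    T = (u[:, :, None] * u[:, None, :]).mean(axis=0)
    lam1 = np.linalg.eigvalsh(T)[-1]
    return float(np.clip(1.5 * (1.0 - lam1), 0.0, 1.0))


@dataclass
class VarianceMap:
    """Per-voxel directional variance in [0, 1], NaN where undefined."""

    values: np.ndarray
    neighborhood_size: int


def _box_sum(a: np.ndarray, size: int) -> np.ndarray:
    # truncated (zero-padded) box-window sum
    return ndi.uniform_filter(a, size=size, mode="constant", cval=0.0) * float(size) ** a.ndim


def local_variance_map(field, neighborhood: int = 21, min_count: int = 10) -> VarianceMap:
    """Directional variance of the valid orientations in each pixel's window.

    2D fields use the doubled-angle circular variance, 3D fields the
    orientation-tensor variance.  Pixels whose window holds fewer than
    ``min_count`` valid orientations get NaN.
    """
    if neighborhood < 1 or neighborhood % 2 == 0:
        raise ValueError("neighborhood must be odd and >= 1")
    valid = field.valid
    vf = valid.astype(np.float64)
    cnt = np.rint(_box_sum(vf, neighborhood))
    out = np.full(valid.shape, np.nan)
    ok = cnt >= max(min_count, 2)
    if not ok.any():
        return VarianceMap(out, neighborhood)

    if field.phi is None:
        tr = np.where(valid, np.radians(2.0 * np.nan_to_num(field.theta)), 0.0)
        c = _box_sum(np.cos(tr) * vf, neighborhood)
        s = _box_sum(np.sin(tr) * vf, neighborhood)
        R = np.hypot(c[ok], s[ok]) / cnt[ok]
        out[ok] = np.clip(1.0 - R, 0.0, 1.0)
    else:
        t = np.radians(np.nan_to_num(field.theta))
        p = np.radians(np.nan_to_num(field.phi))
        ux = np.sin(p) * np.cos(t) * vf
        uy = np.sin(p) * np.sin(t) * vf
        uz = np.cos(p) * vf
        comps = [ux * ux, uy * uy, uz * uz, ux * uy, ux * uz, uy * uz]
        # the products above already vanish off-valid (vf^2 = vf on {0,1})
        sums = [_box_sum(c_, neighborhood) for c_ in comps]
        n = int(ok.sum())
        M = np.empty((n, 3, 3))
        sxx, syy, szz, sxy, sxz, syz = (s_[ok] / cnt[ok] for s_ in sums)
        M[:, 0, 0], M[:, 1, 1], M[:, 2, 2] = sxx, syy, szz
        M[:, 0, 1] = M[:, 1, 0] = sxy
        M[:, 0, 2] = M[:, 2, 0] = sxz
        M[:, 1, 2] = M[:, 2, 1] = syz
        lam1 = np.linalg.eigvalsh(M)[:, -1]
        out[ok] = np.clip(1.5 * (1.0 - lam1), 0.0, 1.0)
    return VarianceMap(out, neighborhood)


def depth_profile(vmap: VarianceMap, spacing_z: float = 1.0) -> pd.DataFrame:
    """Per-slice mean directional variance against physical depth.

    Returns a DataFrame with columns ``depth`` (slice index times
    ``spacing_z``), ``variance_mean`` (NaN for empty slices) and ``n_valid``.
    """
    v = vmap.values
    if v.ndim != 3:
        raise ValueError("depth_profile requires a 3D variance map")
    finite = np.isfinite(v)
    n = finite.sum(axis=(1, 2))
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, np.nansum(np.where(finite, v, 0.0), axis=(1, 2)) / np.maximum(n, 1), np.nan)
    return pd.DataFrame(
        {"depth": np.arange(v.shape[0]) * float(spacing_z), "variance_mean": mean, "n_valid": n}
    )


def stratify_by_thickness(
    field,
    thick,
    edges,
    spacing: float = 1.0,
    neighborhood: int = 21,
    min_count: int = 10,
    bins: int = 20,
    vmap: VarianceMap | None = None,
):
    """Distribution of local directional variance per thickness stratum.

    ``edges`` are physical thickness thresholds (micrometres) splitting the
    foreground into len(edges)+1 strata; ``spacing`` converts them to pixels
    (an edge of 12 um at 0.5 um/px is 24 px).  Returns ``(histograms,
    values)``: a tidy DataFrame of per-stratum probability histograms of V
    over [0, 1], and the raw V samples per stratum label.
    """
    import logging

    edges = [float(e) for e in edges]
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("edges must be strictly increasing")
    t = thick.values if hasattr(thick, "values") else np.asarray(thick)
    if vmap is None:
        vmap = local_variance_map(field, neighborhood, min_count)
    v = vmap.values
    if v.shape != t.shape:
        raise ValueError("field and thickness shapes differ")

    edges_px = [e / float(spacing) for e in edges]
    bounds = [0.0] + edges_px + [np.inf]
    labels, rows, values = [], [], {}
    for lo, hi, lo_u, hi_u in zip(
        bounds[:-1], bounds[1:], [0.0] + edges, edges + [np.inf]
    ):
        sel = (t > lo) & (t <= hi) & np.isfinite(v)
        label = f"({lo_u:g}, {hi_u:g}] um"
        vals = v[sel]
        values[label] = vals
        if vals.size == 0:
            logging.getLogger("fiborient").warning("empty thickness stratum %s", label)
            continue
        counts, bedges = np.histogram(vals, bins=bins, range=(0.0, 1.0))
        prob = counts / counts.sum()
        for bl, br, p in zip(bedges[:-1], bedges[1:], prob):
            rows.append(
                {"stratum": label, "thickness_lo_um": lo_u, "thickness_hi_um": hi_u,
                 "bin_left": bl, "bin_right": br, "probability": p, "n": vals.size}
            )
    return pd.DataFrame(rows), values
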