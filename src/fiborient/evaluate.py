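"""Accuracy evaluation against phantom ground truth.

Provides axial angular error metrics (period-180 wraparound in 2D/per-angle,
axis angle via arccos of the absolute dot product in 3D), per-pixel error
maps, and ``run_comparison`` — the harness that regenerates a phantom suite,
runs the adaptive (window-optimizing) estimator alongside fixed-window
variants, and tabulates mean errors per method, window and diameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import phantoms
from .orientation import OrientationField, OrientationParams, orient
from .thickness import local_thickness


class EmptyOverlapError(ValueError):
    """Truth mask and valid estimates do not overlap."""


def angular_error_axial(a, b):
    """Axial angular difference in degrees, in [0, 90] (period 180)."""
    d = np.abs(np.asarray(a, float) - np.asarray(b, float)) % 180.0
    return np.minimum(d, 180.0 - d)


def axis_error_3d(theta_a, phi_a, theta_b, phi_b):
    """Angle between two 3D axes given as (theta, phi) degrees; in [0, 90]."""
    ta, pa = np.radians(np.asarray(theta_a, float)), np.radians(np.asarray(phi_a, float))
    tb, pb = np.radians(np.asarray(theta_b, float)), np.radians(np.asarray(phi_b, float))
    dot = (
        np.sin(pa) * np.cos(ta) * np.sin(pb) * np.cos(tb)
        + np.sin(pa) * np.sin(ta) * np.sin(pb) * np.sin(tb)
        + np.cos(pa) * np.cos(pb)
    )
    return np.degrees(np.arccos(np.clip(np.abs(dot), 0.0, 1.0)))


@dataclass
class ErrorMap:
    """Per-pixel angular error in degrees; NaN outside truth-mask ∩ valid."""

    values: np.ndarray
    kind: str  # theta2d | theta3d | phi3d | axis3d


def error_map(field: OrientationField, truth: phantoms.PhantomTruth, kind: str) -> ErrorMap:
    """Per-pixel angular error of an orientation field against truth."""
    overlap = truth.mask & field.valid
    if not overlap.any():
        raise EmptyOverlapError("no overlap between truth mask and valid estimates")
    out = np.full(truth.mask.shape, np.nan)
    if kind in ("theta2d", "theta3d"):
        out[overlap] = angular_error_axial(field.theta[overlap], truth.theta[overlap])
    elif kind == "phi3d":
        out[overlap] = angular_error_axial(field.phi[overlap], truth.phi[overlap])
    elif kind == "axis3d":
        out[overlap] = axis_error_3d(
            field.theta[overlap], field.phi[overlap], truth.theta[overlap], truth.phi[overlap]
        )
    else:
        raise ValueError(f"unknown error kind {kind!r}")
    return ErrorMap(out, kind)


@dataclass
class ComparisonReport:
    """Mean-error tables from a phantom comparison run.

    ``summary`` has one row per (method, window, kind) with the across-image
    mean of per-image mean errors and the pixel-pooled mean; ``per_image``
    and ``per_diameter`` break the same errors down.  Fully reproducible from
    (spec, window_sizes, n_images, seed).
    """

    summary: pd.DataFrame
    per_image: pd.DataFrame
    per_diameter: pd.DataFrame
    n_images: int
    seed: int

    def mean_error(self, method: str, kind: str, window: int = 0) -> float:
        s = self.summary
        row = s[(s.method == method) & (s.kind == kind) & (s.window == window)]
        return float(row.mean_error_deg.iloc[0])

    def save(self, outdir) -> None:
        from pathlib import Path
        import json

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.summary.to_csv(outdir / "summary.csv", index=False)
        self.per_image.to_csv(outdir / "per_image.csv", index=False)
        self.per_diameter.to_csv(outdir / "per_diameter.csv", index=False)
        head = {
            "n_images": self.n_images,
            "seed": self.seed,
            "wo": {
                k: self.mean_error("wo", k)
                for k in self.summary[self.summary.method == "wo"].kind.unique()
            },
        }
        (outdir / "report.json").write_text(json.dumps(head, indent=2))


def _error_kinds(is3d: bool):
    return ("theta3d", "phi3d", "axis3d") if is3d else ("theta2d",)


def _field_errors(fld, truth, is3d):
    out = {}
    for kind in _error_kinds(is3d):
        em = error_map(fld, truth, kind).values
        out[kind] = em
    return out


def run_comparison(
    spec: phantoms.PhantomSpec,
    window_sizes=(21, 41, 81, 121, 161, 201),
    n_images: int = 4,
    seed: int | None = None,
    params: OrientationParams | None = None,
) -> ComparisonReport:
    """Regenerate phantoms and score adaptive vs fixed-window orientation.

    Images use seeds ``seed .. seed + n_images - 1`` (``seed`` defaults to
    ``spec.seed``).  For every image the pipeline is: generate -> local
    thickness -> orientation (adaptive, then each fixed window) -> per-pixel
    angular error on truth-mask ∩ valid pixels.  Mean errors are reported
    both per-image-then-averaged and pixel-pooled; pixels within one
    diameter of a fiber endpoint (the image border, since phantom fibers
    span the frame) are additionally summarized separately.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    seed = spec.seed if seed is None else int(seed)
    base = params or OrientationParams()
    is3d = len(spec.dims) == 3

    img_rows, diam_rows = [], []
    for i in range(n_images):
        sp = replace(spec, seed=seed + i)
        img, truth = phantoms.generate(sp)
        tmap = local_thickness(truth.mask)
        fields = {("wo", 0): orient(img, truth.mask, tmap, replace(base, mode="wo", fixed_window=None))}
        for w in window_sizes:
            p = replace(base, mode="fixed", fixed_window=int(w))
            if int(w) >= min(truth.mask.shape):
                # an oversized window sees the whole frame from every pixel;
                # the full-fit validity rule would void the field entirely
                p = replace(p, require_full_window=False)
            fields[("fixed", int(w))] = orient(img, truth.mask, None, p)

        border = _border_distance(truth.mask.shape)
        near_end = border < truth.thickness  # fibers span the frame; ends sit on it
        for (method, w), fld in fields.items():
            errs = _field_errors(fld, truth, is3d)
            for kind, em in errs.items():
                fin = np.isfinite(em)
                img_rows.append(
                    {
                        "image": i, "method": method, "window": w, "kind": kind,
                        "mean_error_deg": float(em[fin].mean()),
                        "mean_error_interior_deg": float(em[fin & ~near_end].mean())
                        if (fin & ~near_end).any() else np.nan,
                        "n_pixels": int(fin.sum()),
                        "n_mask": int(truth.mask.sum()),
                        "n_near_endpoint": int((fin & near_end).sum()),
                    }
                )
                for D in np.unique(truth.thickness[truth.mask]):
                    seld = fin & (truth.thickness == D)
                    if seld.any():
                        diam_rows.append(
                            {
                                "image": i, "method": method, "window": w, "kind": kind,
                                "diameter": float(D),
                                "mean_error_deg": float(em[seld].mean()),
                                "n_pixels": int(seld.sum()),
                            }
                        )

    per_image = pd.DataFrame(img_rows)
    per_diameter = (
        pd.DataFrame(diam_rows)
        .groupby(["method", "window", "kind", "diameter"], as_index=False)
        .agg(mean_error_deg=("mean_error_deg", "mean"), n_pixels=("n_pixels", "sum"))
    )
    summary = _summary_frame(per_image.groupby(["method", "window", "kind"]))
    return ComparisonReport(summary, per_image, per_diameter, n_images, seed)


def _summary_frame(grouped) -> pd.DataFrame:
    rows = []
    for (method, window, kind), df in grouped:
        rows.append(
            {
                "method": method, "window": window, "kind": kind,
                "mean_error_deg": df.mean_error_deg.mean(),
                "pooled_error_deg": float(np.average(df.mean_error_deg, weights=df.n_pixels)),
                "mean_error_interior_deg": df.mean_error_interior_deg.mean(),
                "n_pixels": int(df.n_pixels.sum()),
            }
        )
    return pd.DataFrame(rows)


def _border_distance(shape) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    d = np.full(shape, np.inf)
    for g, n in zip(grids, shape):
        d = np.minimum(d, np.minimum(g, n - 1 - g))
    return d
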