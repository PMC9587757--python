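"""Image containers, TIFF I/O, binarization and export helpers.

Arrays are indexed ``(z,)y,x``: ``x`` is the image column, ``y`` the row and
``z`` the slice (depth) index.  All angle conventions elsewhere in the package
refer to this frame.  Orientation maps are stored numerically as 32-bit float
TIFF in degrees with NaN marking invalid pixels; PNG export is visualization
only.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np
import tifffile
from skimage.filters import threshold_otsu

logger = logging.getLogger("fiborient")


class FormatError(ValueError):
    """Raised for unsupported or malformed image data."""


@dataclass
class ImageStack:
    """A 2D image or 3D image stack of scalar intensities.

    Parameters
    ----------
    values
        2D ``(y, x)`` or 3D ``(z, y, x)`` array of finite scalars.
    spacing
        Physical size of one pixel/voxel along each axis (same order as the
        array axes), e.g. micrometres per pixel.  Defaults to 1 per axis.
    """

    values: np.ndarray
    spacing: tuple[float, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim not in (2, 3):
            raise FormatError(f"expected 2D or 3D data, got {self.values.ndim}D")
        if np.isinf(self.values).any():
            raise FormatError("image values must not be infinite")
        # NaN is allowed: orientation/variance maps use it to mark invalid
        if self.spacing is None:
            self.spacing = (1.0,) * self.values.ndim
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != self.values.ndim:
            raise FormatError("spacing must have one entry per axis")
        if any(s <= 0 for s in self.spacing):
            raise FormatError("spacing entries must be > 0")

    @property
    def ndim(self) -> int:
        return self.values.ndim

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


@dataclass
class BinaryMask:
    """Boolean foreground mask co-registered with an :class:`ImageStack`."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim not in (2, 3):
            raise FormatError(f"expected 2D or 3D mask, got {self.values.ndim}D")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


def read_stack(path, spacing=None) -> ImageStack:
    """Read a single- or multi-page grayscale TIFF.

    A one-page file yields a 2D stack; a multi-page file becomes 3D with the
    page index as ``z``.  Integer dtypes are preserved.
    """
    arr = tifffile.imread(path)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.shape[0] not in (3, 4):
        raise FormatError(f"{path}: color TIFFs are not supported (grayscale only)")
    if arr.ndim not in (2, 3):
        raise FormatError(f"{path}: unsupported TIFF dimensionality {arr.ndim}")
    return ImageStack(arr, spacing=spacing)


def write_stack(img: ImageStack | np.ndarray, path) -> None:
    """Write an image (2D) or stack (3D, multi-page) as TIFF.

    Float data is written as 32-bit; NaNs are preserved.
    """
    arr = img.values if hasattr(img, "values") else np.asarray(img)
    if np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(np.float32)
    tifffile.imwrite(path, arr)


def binarize(img: ImageStack, method: str = "otsu", threshold: float | None = None) -> BinaryMask:
    """Threshold an intensity image into a foreground mask.

    ``otsu`` computes a single Otsu threshold on the whole stack (not per
    slice); ``fixed`` uses the supplied ``threshold``.  Foreground is strictly
    above the threshold.
    """
    vals = img.values
    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires a threshold")
        thr = float(threshold)
    elif method == "otsu":
        if np.ptp(vals) == 0:
            raise ValueError("cannot Otsu-threshold a constant image")
        thr = float(threshold_otsu(vals))
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    return BinaryMask(vals > thr)


def export_orientation_png(field, path, angle: str = "theta", legend_path=None) -> None:
    """Render an orientation field as a hue-coded PNG.

    Hue encodes the angle cyclically over [0, 180) so that 0 and 180-epsilon
    map to nearly the same color (axial data); invalid pixels are black.  A
    color-wheel legend is written alongside (``<path>.legend.png`` unless
    ``legend_path`` is given).
    """
    import matplotlib

    matplotlib.use("Agg")
    from matplotlib import pyplot as plt
    from matplotlib.colors import hsv_to_rgb

    ang = getattr(field, angle)
    if ang is None:
        raise ValueError(f"field has no {angle!r} component")
    ang = np.asarray(ang, dtype=float)
    if ang.ndim == 3:  # mid-slice preview for stacks
        ang = ang[ang.shape[0] // 2]
    valid = np.isfinite(ang)
    hue = np.where(valid, (ang % 180.0) / 180.0, 0.0)
    hsv = np.stack([hue, np.ones_like(hue), valid.astype(float)], axis=-1)
    rgb = hsv_to_rgb(hsv)
    plt.imsave(path, rgb)

    # color wheel legend: angle of each pixel around the center, axial period
    n = 201
    yy, xx = np.mgrid[-1 : 1 : n * 1j, -1 : 1 : n * 1j]
    r = np.hypot(xx, yy)
    wheel_ang = (np.degrees(np.arctan2(yy, xx)) % 180.0) / 180.0
    inside = (r <= 1.0) & (r >= 0.45)
    hsv_w = np.stack([wheel_ang, np.ones_like(wheel_ang), inside.astype(float)], axis=-1)
    lp = legend_path if legend_path is not None else str(path) + ".legend.png"
    plt.imsave(lp, hsv_to_rgb(hsv_w))


def export_histogram(values, path, bins: int = 18, range=(0.0, 180.0)) -> "pd.DataFrame":
    """Write a probability histogram as CSV (bin_left, bin_right, probability).

    Probabilities are normalized to sum to 1 over the non-empty input.
    """
    import pandas as pd

    vals = np.asarray(values, dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("cannot histogram empty input")
    if bins < 1:
        raise ValueError("bins must be >= 1")
    counts, edges = np.histogram(vals, bins=bins, range=range)
    prob = counts / counts.sum() if counts.sum() else counts.astype(float)
    df = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "probability": prob}
    )
    if path is not None:
        df.to_csv(path, index=False, quoting=csv.QUOTE_MINIMAL)
    return df
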