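"""Raster image I/O and the pixel-feature containers used across the package.

Images are held as flat ``N x D`` feature matrices (``N = height * width``
pixels in row-major order, ``D`` intensity channels) so that clustering code
never needs to know about the grid except through the neighborhood system.
Intensities stay in their native storage units (0-255 for 8-bit input); the
spatial-regularization hyperparameters shipped with the segmenters are
calibrated against squared distances on that scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np

__all__ = [
    "FeatureImage",
    "LabelMap",
    "read_image",
    "read_label_map",
    "write_label_map",
    "write_image",
    "class_mean_reconstruction",
    "write_metrics",
]


@dataclass(frozen=True)
class FeatureImage:
    """A raster image as an ``N x D`` feature matrix with its grid shape.

    Parameters
    ----------
    height, width : int
        Grid shape; pixel linear index ``i = r * width + c`` (row-major).
    values : ndarray, shape (N, D)
        Per-pixel feature vectors in native intensity units.
    intensity_range : tuple of float
        ``(min, max)`` of the storage format, ``(0, 255)`` for 8-bit.
    """

    height: int
    width: int
    values: np.ndarray
    intensity_range: tuple[float, float] = (0.0, 255.0)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim == 1:
            vals = vals[:, None]
        if vals.shape[0] != self.height * self.width:
            raise ValueError(
                f"values has {vals.shape[0]} rows, expected "
                f"{self.height}*{self.width}={self.height * self.width}"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError("feature values must be finite")
        object.__setattr__(self, "values", vals)

    @property
    def n_pixels(self) -> int:
        return self.height * self.width

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    def to_grid(self) -> np.ndarray:
        """Return the image as an ``(height, width)`` or ``(height, width, D)`` array."""
        grid = self.values.reshape(self.height, self.width, self.n_channels)
        return grid[:, :, 0] if self.n_channels == 1 else grid

    @classmethod
    def from_array(cls, arr: np.ndarray, intensity_range=(0.0, 255.0)) -> "FeatureImage":
        """Build a FeatureImage from an ``(H, W)`` or ``(H, W, D)`` array."""
        arr = np.asarray(arr, dtype=float)
        if arr.ndim == 2:
            arr = arr[:, :, None]
        if arr.ndim != 3 or arr.size == 0:
            raise ValueError("expected a non-empty (H, W) or (H, W, D) array")
        h, w, d = arr.shape
        return cls(h, w, arr.reshape(h * w, d), intensity_range)


@dataclass(frozen=True)
class LabelMap:
    """Integer class labels on the same grid as a :class:`FeatureImage`."""

    height: int
    width: int
    labels: np.ndarray
    n_classes: int

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels).reshape(-1).astype(np.int64)
        if lab.size != self.height * self.width:
            raise ValueError("label count does not match the grid shape")
        if lab.size and (lab.min() < 0 or lab.max() >= self.n_classes):
            raise ValueError(f"labels must lie in 0..{self.n_classes - 1}")
        object.__setattr__(self, "labels", lab)

    def to_grid(self) -> np.ndarray:
        return self.labels.reshape(self.height, self.width)


def read_image(path, as_gray: bool = False) -> FeatureImage:
    """Read a PNG/TIFF/PGM raster into a :class:`FeatureImage`.

    ``D = 1`` for grayscale input or when *as_gray* is set (RGB is converted
    with the standard luma transform); RGB input keeps ``D = 3``.
    """
    try:
        if as_gray:
            arr = iio.imread(path, plugin="pillow", mode="L")
        else:
            arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # truncated / undecodable file
        raise ValueError(f"cannot decode image file {path!r}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.size == 0:
        raise ValueError(f"image {path!r} has zero area")
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    peak = 65535.0 if arr.dtype == np.uint16 else 255.0
    return FeatureImage.from_array(arr, intensity_range=(0.0, peak))


def default_palette(n_classes: int) -> np.ndarray:
    """Evenly spread ``C`` classes over 0..255: class j -> round(255 j/(C-1))."""
    if n_classes <= 1:
        return np.zeros(max(n_classes, 1), dtype=np.uint8)
    return np.round(255.0 * np.arange(n_classes) / (n_classes - 1)).astype(np.uint8)


def write_label_map(labels: LabelMap, path, palette=None) -> None:
    """Write a label map as an 8-bit grayscale image."""
    pal = default_palette(labels.n_classes) if palette is None else np.asarray(palette, dtype=np.uint8)
    iio.imwrite(path, pal[labels.to_grid()])


def read_label_map(path, n_classes: int | None = None) -> LabelMap:
    """Read a grayscale label image, mapping sorted distinct gray values to 0..C-1."""
    img = read_image(path, as_gray=True)
    grid = img.to_grid()
    values = np.unique(grid)
    labels = np.searchsorted(values, grid)
    c = len(values) if n_classes is None else n_classes
    return LabelMap(img.height, img.width, labels, c)


def write_image(image: FeatureImage, path) -> None:
    """Write a FeatureImage as an 8-bit raster (values rounded and clipped)."""
    lo, hi = image.intensity_range
    arr = np.clip(np.round(image.to_grid()), lo, hi).astype(np.uint8)
    iio.imwrite(path, arr)


def class_mean_reconstruction(image: FeatureImage, labels: LabelMap) -> FeatureImage:
    """Replace every pixel by the mean of all pixels sharing its label.

    The piecewise-constant reconstruction used by the PSNR segmentation-quality
    protocol; idempotent for fixed labels.
    """
    if (image.height, image.width) != (labels.height, labels.width):
        raise ValueError("image and label map shapes disagree")
    lab = labels.labels
    counts = np.bincount(lab, minlength=labels.n_classes).astype(float)
    out = np.empty_like(image.values)
    for l in range(image.n_channels):
        sums = np.bincount(lab, weights=image.values[:, l], minlength=labels.n_classes)
        means = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
        out[:, l] = means[lab]
    return FeatureImage(image.height, image.width, out, image.intensity_range)


def write_metrics(path, *, psnr_db: float, mcr_percent: float,
                  iterations: int, converged: bool, **extra) -> None:
    """Serialize a run's metrics to JSON (``inf`` PSNR written as the string "inf")."""
    record = {
        "psnr_db": "inf" if math.isinf(psnr_db) else float(psnr_db),
        "mcr_percent": float(mcr_percent),
        "iterations": int(iterations),
        "converged": bool(converged),
    }
    record.update(extra)
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2)
        fh.write("\n")
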