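"""Ground-truth phantoms and the noise models used to stress the segmenters.

Phantoms are piecewise-constant multi-class images (stripes, quadrants or
Voronoi blobs) with known gray levels per class — surrogates for the kind
of artificial multi-category scenes segmentation benchmarks use. The noise
operators cover additive Gaussian, impulse (salt-and-pepper), multiplicative
(speckle) and Gaussian+impulse mixtures; noise magnitudes are standard
deviations on the 0-255 intensity scale, and every operator clips back into
the image's intensity range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_io import FeatureImage, LabelMap

__all__ = [
    "Phantom",
    "make_phantom",
    "default_levels",
    "add_gaussian",
    "add_salt_pepper",
    "add_multiplicative",
    "add_mixed",
]


@dataclass(frozen=True)
class Phantom:
    """A clean piecewise-constant image with its ground-truth label map."""

    image: FeatureImage
    truth: LabelMap
    class_levels: tuple[float, ...]

    @property
    def n_classes(self) -> int:
        return self.truth.n_classes


def default_levels(n_classes: int) -> tuple[float, ...]:
    """Evenly spaced interior gray levels, away from the 0/255 impulse extremes."""
    return tuple(np.round(np.linspace(40.0, 210.0, n_classes)))


def make_phantom(height: int, width: int, C: int, levels=None,
                 layout: str = "stripes", seed: int = 0) -> Phantom:
    """Generate a C-class piecewise-constant phantom.

    Layouts: ``stripes`` (horizontal bands of equal height), ``quadrants``
    (the four image quadrants, classes assigned cyclically; C <= 4) and
    ``blobs`` (Voronoi cells of C seeded random sites). Every class covers
    at least 5% of the pixels; deterministic given *seed*.
    """
    if levels is None:
        levels = default_levels(C)
    levels = tuple(float(v) for v in levels)
    if len(levels) != C:
        raise ValueError(f"need exactly {C} gray levels, got {len(levels)}")
    if any(b <= a for a, b in zip(levels, levels[1:])):
        raise ValueError("class levels must be strictly increasing")
    if not all(0 <= v <= 255 for v in levels):
        raise ValueError("class levels must lie in [0, 255]")

    if layout == "stripes":
        if C > height:
            raise ValueError(f"stripes layout needs height >= C (got {height} < {C})")
        rows = np.minimum(np.arange(height) * C // height, C - 1)
        labels = np.repeat(rows, width)
    elif layout == "quadrants":
        if not 2 <= C <= 4:
            raise ValueError("quadrants layout supports 2-4 classes")
        rr, cc = np.divmod(np.arange(height * width), width)
        quad = 2 * (rr >= height // 2) + (cc >= width // 2)
        labels = quad % C
    elif layout == "blobs":
        rng = np.random.default_rng(seed)
        n = height * width
        rr, cc = np.divmod(np.arange(n), width)
        for _ in range(100):
            sites = np.column_stack([rng.uniform(0, height, C),
                                     rng.uniform(0, width, C)])
            d2 = (rr[:, None] - sites[None, :, 0]) ** 2 \
                + (cc[:, None] - sites[None, :, 1]) ** 2
            labels = np.argmin(d2, axis=1)
            counts = np.bincount(labels, minlength=C)
            if counts.min() >= 0.05 * n:
                break
        else:
            raise ValueError("could not place blobs giving every class >= 5% coverage")
    else:
        raise ValueError(f"unknown layout {layout!r}")

    truth = LabelMap(height, width, labels, C)
    values = np.asarray(levels)[labels][:, None]
    counts = np.bincount(truth.labels, minlength=C)
    if counts.min() < 0.05 * height * width:
        raise ValueError("layout infeasible: a class covers less than 5% of pixels")
    return Phantom(FeatureImage(height, width, values), truth, levels)


def _clip(values: np.ndarray, image: FeatureImage) -> FeatureImage:
    lo, hi = image.intensity_range
    return FeatureImage(image.height, image.width,
                        np.clip(values, lo, hi), image.intensity_range)


def add_gaussian(image: FeatureImage, sigma: float, seed: int = 0,
                 sigma_is_variance: bool = False) -> FeatureImage:
    """Add zero-mean i.i.d. Gaussian noise of standard deviation *sigma*.

    Noise levels quoted as "variance" in segmentation benchmarks are almost
    always standard deviations on the 0-255 scale; set *sigma_is_variance*
    to treat *sigma* as a true variance instead.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    sd = np.sqrt(sigma) if sigma_is_variance else sigma
    rng = np.random.default_rng(seed)
    noisy = image.values + rng.normal(0.0, sd, size=image.values.shape) if sd > 0 \
        else image.values.copy()
    return _clip(noisy, image)


def add_salt_pepper(image: FeatureImage, density: float, seed: int = 0) -> FeatureImage:
    """Replace an exact fraction *density* of pixels by the intensity extremes.

    Exactly round(density * N) pixels are chosen by a seeded permutation;
    each corrupted pixel independently becomes the range minimum (pepper)
    or maximum (salt) with equal probability, across all channels.
    """
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = image.n_pixels
    n_corrupt = int(round(density * n))
    values = image.values.copy()
    if n_corrupt:
        pick = rng.permutation(n)[:n_corrupt]
        lo, hi = image.intensity_range
        salt = rng.random(n_corrupt) < 0.5
        values[pick] = np.where(salt[:, None], hi, lo)
    return FeatureImage(image.height, image.width, values, image.intensity_range)


def add_multiplicative(image: FeatureImage, sigma: float, seed: int = 0) -> FeatureImage:
    """Speckle noise: out = in * (1 + n), n ~ Normal(0, (sigma/255)^2).

    *sigma* is quoted on the 0-255 intensity scale so that speckle and
    additive Gaussian levels are comparable on an 8-bit image.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    rng = np.random.default_rng(seed)
    rel = sigma / 255.0
    noisy = image.values * (1.0 + rng.normal(0.0, rel, size=image.values.shape)) \
        if rel > 0 else image.values.copy()
    return _clip(noisy, image)


def add_mixed(image: FeatureImage, sigma_gauss: float, sp_density: float,
              seed: int = 0, gaussian_first: bool = True) -> FeatureImage:
    """Gaussian plus salt-and-pepper noise.

    Gaussian is applied first by default so the impulse pixels stay at the
    pure extremes; sub-seeds for the two stages derive deterministically
    from *seed*.
    """
    s1, s2 = _split_seed(seed, 2)
    if gaussian_first:
        return add_salt_pepper(add_gaussian(image, sigma_gauss, s1), sp_density, s2)
    return add_gaussian(add_salt_pepper(image, sp_density, s2), sigma_gauss, s1)


def _split_seed(seed: int, n: int) -> list[int]:
    """Derive n independent sub-seeds (< 2^31) from one integer seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]
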