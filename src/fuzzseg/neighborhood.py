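"""Spatial neighborhood system shared by every clusterer.

For each pixel i the system provides its neighbor set N_i (the pixels inside
an odd square window centered on i, excluding i itself) together with the
Euclidean distances between grid coordinates — so 1 and sqrt(2) in a 3x3
window. Pixels at the image border simply have fewer neighbors (truncation;
no padding or mirroring, which would invent pixel values).

Internally neighbors are stored per window *offset*: ``index[k]`` maps every
pixel to its neighbor under offset k (self where the offset falls outside the
grid) and ``valid[k]`` masks the in-bounds entries. Gathering a per-pixel
field through ``index`` and masking with ``valid`` turns every sum over N_i
into a handful of vectorized array operations.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Neighborhood", "build_neighborhood", "neighbor_weights_flicm"]


class Neighborhood:
    """Neighbor indices and spatial distances for an H x W grid.

    Parameters
    ----------
    height, width : int
        Grid shape.
    window : int
        Odd window side length (3 or 5 in practice).
    """

    def __init__(self, height: int, width: int, window: int = 3):
        if window % 2 == 0 or window < 3:
            raise ValueError(f"window must be an odd integer >= 3, got {window}")
        if height < 1 or width < 1:
            raise ValueError("grid must have positive area")
        self.height = int(height)
        self.width = int(width)
        self.window = int(window)

        half = window // 2
        offsets = [
            (dr, dc)
            for dr in range(-half, half + 1)
            for dc in range(-half, half + 1)
            if (dr, dc) != (0, 0)
        ]
        self.offsets = np.array(offsets, dtype=int)  # (K, 2)
        self.distances = np.hypot(self.offsets[:, 0], self.offsets[:, 1]).astype(float)

        n = height * width
        rr, cc = np.divmod(np.arange(n), width)
        idx = np.empty((len(offsets), n), dtype=np.intp)
        valid = np.empty((len(offsets), n), dtype=bool)
        for k, (dr, dc) in enumerate(offsets):
            r2, c2 = rr + dr, cc + dc
            ok = (0 <= r2) & (r2 < height) & (0 <= c2) & (c2 < width)
            valid[k] = ok
            idx[k] = np.where(ok, r2 * width + c2, np.arange(n))
        self.index = idx     # (K, N) neighbor linear index per offset
        self.valid = valid   # (K, N) in-bounds mask

    @property
    def n_pixels(self) -> int:
        return self.height * self.width

    @property
    def n_offsets(self) -> int:
        return len(self.distances)

    def neighbor_counts(self) -> np.ndarray:
        """|N_i| per pixel (w^2 - 1 in the interior, fewer at borders)."""
        return self.valid.sum(axis=0)

    def neighbors(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(indices, distances)`` of the in-bounds neighbors of pixel i."""
        if not 0 <= i < self.n_pixels:
            raise IndexError(f"pixel index {i} out of range for N={self.n_pixels}")
        ok = self.valid[:, i]
        return self.index[ok, i], self.distances[ok]

    def gather(self, field: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Gather *field* (shape ``(N, ...)``) at every neighbor.

        Returns ``(values, mask)`` with ``values`` of shape ``(K, N, ...)``
        (entries under out-of-bounds offsets are the pixel's own value and
        must be masked) and ``mask`` of shape ``(K, N)``.
        """
        return field[self.index], self.valid


def build_neighborhood(height: int, width: int, window: int = 3) -> Neighborhood:
    """Construct the neighborhood system for an ``height x width`` grid."""
    return Neighborhood(height, width, window)


def neighbor_weights_flicm(spec: Neighborhood, i: int) -> list[tuple[int, float]]:
    """Inverse-distance weights ``(beta, 1/d_ib)`` over the neighbors of pixel i."""
    idx, dist = spec.neighbors(i)
    return [(int(b), 1.0 / d) for b, d in zip(idx, dist)]
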