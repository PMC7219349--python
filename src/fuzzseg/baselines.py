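"""Fuzzy c-means segmenters: FCM, FLICM, and a membership-constrained FLICM.

FCM alternates the classic membership / center updates on pixel intensities
alone. FLICM adds a fuzzy factor G_ij that penalizes assigning pixel i to
class j when its spatial neighbors resist that class,

    G_ij = sum_{b in N_i} w(d_ib) (1 - z_bj)^m ||x_b - v_j||^2 ,

with inverse-distance-like weights w(d) = 1/(d+1) (a flag selects 1/d).
The membership-constrained variant further divides each neighbor's weight by
(z_bj * d_ib + 1), so confident neighbors at a distance count less, and mixes
the neighborhood into the center update itself — the exact stationary point
of the Lagrangian rather than the plain FCM center.

All three share one alternating-optimization engine, so FLICM with its
spatial term disabled reproduces FCM bit-for-bit under the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image_io import FeatureImage, LabelMap
from .neighborhood import Neighborhood

__all__ = [
    "FCM",
    "FLICM",
    "MembershipConstrainedFLICM",
    "FuzzyResults",
    "fcm",
    "flicm",
    "improved_flicm",
    "flicm_fuzzy_factor",
]

_TINY = 1e-300
_MEMBERSHIP_FLOOR = 1e-12


def _as_feature_image(image) -> FeatureImage:
    if isinstance(image, FeatureImage):
        return image
    return FeatureImage.from_array(np.asarray(image))


def initial_memberships(n_pixels: int, n_classes: int, seed: int) -> np.ndarray:
    """Uniform random memberships, rows normalized; deterministic given seed."""
    rng = np.random.default_rng(seed)
    z = rng.random((n_pixels, n_classes))
    return z / z.sum(axis=1, keepdims=True)


def memberships_from_dissimilarity(D: np.ndarray, m: float) -> np.ndarray:
    """Fuzzy memberships z_ij = D_ij^{-1/(m-1)} / sum_k D_ik^{-1/(m-1)}.

    A pixel with zero dissimilarity to some class gets membership 1 there
    (first such class on ties — the standard singular-distance convention).
    """
    z = np.zeros_like(D)
    singular = D <= _TINY
    crisp = singular.any(axis=1)
    if crisp.any():
        rows = np.where(crisp)[0]
        z[rows, np.argmax(singular[rows], axis=1)] = 1.0
    ok = ~crisp
    if ok.any():
        p = D[ok] ** (-1.0 / (m - 1.0))
        z[ok] = p / p.sum(axis=1, keepdims=True)
    return z


def _pairwise_sq_dist(X: np.ndarray, v: np.ndarray) -> np.ndarray:
    """(N, C) squared Euclidean distances between pixels and centers."""
    return ((X[:, None, :] - v[None, :, :]) ** 2).sum(axis=-1)


def _fcm_centers(X: np.ndarray, z: np.ndarray, m: float, prev: np.ndarray) -> np.ndarray:
    zm = z ** m
    weights = zm.sum(axis=0)
    v = prev.copy()
    ok = weights > _MEMBERSHIP_FLOOR
    v[ok] = (zm.T @ X)[ok] / weights[ok, None]
    return v


@dataclass
class FuzzyResults:
    """Converged state of a fuzzy c-means style segmenter.

    Attributes
    ----------
    z : ndarray, shape (N, C)
        Final fuzzy memberships; rows sum to 1.
    centers : ndarray, shape (C, D)
        Cluster centers in intensity units.
    objective_trace : list of float
        Objective value after each full iteration.
    """

    image: FeatureImage
    z: np.ndarray
    centers: np.ndarray
    m: float
    n_iter: int
    converged: bool
    objective_trace: list[float] = field(default_factory=list)
    algorithm: str = "fcm"

    def labels(self) -> np.ndarray:
        """Max-membership labels; ties broken toward the lowest class index."""
        return np.argmax(self.z, axis=1)

    def label_map(self) -> LabelMap:
        return LabelMap(self.image.height, self.image.width,
                        self.labels(), self.z.shape[1])

    def summary(self) -> str:
        lines = [
            f"{self.algorithm.upper()} segmentation results",
            "=" * 40,
            f"pixels:            {self.image.n_pixels}",
            f"classes:           {self.z.shape[1]}",
            f"fuzzifier m:       {self.m:g}",
            f"iterations:        {self.n_iter}",
            f"converged:         {self.converged}",
            f"final objective:   {self.objective_trace[-1]:.6g}"
            if self.objective_trace else "final objective:   n/a",
            "centers (intensity units):",
        ]
        for j, row in enumerate(self.centers):
            lines.append(f"  class {j}: " + ", ".join(f"{x:.2f}" for x in row))
        return "\n".join(lines)


class FCM:
    """Fuzzy c-means model for a pixel-feature image.

    Parameters
    ----------
    image : FeatureImage or array
        Input image; arrays are wrapped via :meth:`FeatureImage.from_array`.
    n_classes : int
        Number of clusters C (2 <= C <= N).
    m : float
        Fuzzifier exponent, > 1.
    tol : float
        Convergence threshold on max |z change| between iterations.
    max_iter : int
        Iteration cap; hitting it is reported via ``converged=False``.
    """

    algorithm = "fcm"

    def __init__(self, image, n_classes: int, *, m: float = 2.0,
                 tol: float = 1e-4, max_iter: int = 300):
        self.image = _as_feature_image(image)
        if not 2 <= n_classes <= self.image.n_pixels:
            raise ValueError(f"n_classes must be in [2, {self.image.n_pixels}]")
        if m <= 1:
            raise ValueError("fuzzifier m must exceed 1")
        self.n_classes = int(n_classes)
        self.m = float(m)
        self.tol = float(tol)
        self.max_iter = int(max_iter)

    # Spatial term; overridden by the FLICM variants.
    def _fuzzy_factor(self, X, z, v):
        return 0.0

    def _centers(self, X, z, v_prev):
        return _fcm_centers(X, z, self.m, v_prev)

    def fit(self, seed: int = 0) -> FuzzyResults:
        """Run alternating optimization from a seeded random membership init."""
        X = self.image.values
        z = initial_memberships(self.image.n_pixels, self.n_classes, seed)
        # Initial centers from the plain weighted-mean formula for every variant.
        v = _fcm_centers(X, z, self.m, X.mean(axis=0)[None, :].repeat(self.n_classes, 0))
        trace: list[float] = []
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            G = self._fuzzy_factor(X, z, v)
            D = _pairwise_sq_dist(X, v) + G
            z_new = memberships_from_dissimilarity(D, self.m)
            v = self._centers(X, z_new, v)
            trace.append(self._objective(X, z_new, v))
            delta = np.abs(z_new - z).max()
            z = z_new
            if delta < self.tol:
                converged = True
                break
        return FuzzyResults(self.image, z, v, self.m, it, converged, trace,
                            algorithm=self.algorithm)

    def _objective(self, X, z, v) -> float:
        G = self._fuzzy_factor(X, z, v)
        return float((z ** self.m * (_pairwise_sq_dist(X, v) + G)).sum())


class FLICM(FCM):
    """FLICM: fuzzy local information c-means.

    Adds the neighborhood fuzzy factor G_ij to the FCM dissimilarity. Pass
    ``window=None`` to disable the spatial term entirely (exact FCM).

    Parameters
    ----------
    window : int or None
        Odd window side (3 or 5); None disables the neighborhood term.
    neighborhood : Neighborhood, optional
        Prebuilt neighborhood system; overrides *window*.
    inverse_distance : bool
        Use 1/d neighbor weights instead of the default 1/(d+1).
    """

    algorithm = "flicm"

    def __init__(self, image, n_classes: int, *, m: float = 2.0,
                 tol: float = 1e-4, max_iter: int = 300,
                 window: int | None = 3, neighborhood: Neighborhood | None = None,
                 inverse_distance: bool = False):
        super().__init__(image, n_classes, m=m, tol=tol, max_iter=max_iter)
        if neighborhood is None and window is not None:
            neighborhood = Neighborhood(self.image.height, self.image.width, window)
        self.neighborhood = neighborhood
        self.inverse_distance = bool(inverse_distance)

    def _neighbor_weights(self):
        d = self.neighborhood.distances
        return 1.0 / d if self.inverse_distance else 1.0 / (d + 1.0)

    def _fuzzy_factor(self, X, z, v):
        nb = self.neighborhood
        if nb is None:
            return 0.0
        F = (1.0 - z) ** self.m * _pairwise_sq_dist(X, v)  # (N, C)
        Fg, mask = nb.gather(F)
        w = self._neighbor_weights()
        return (w[:, None, None] * Fg * mask[:, :, None]).sum(axis=0)


class MembershipConstrainedFLICM(FLICM):
    """FLICM with membership-constrained neighbor weights and exact centers.

    The fuzzy factor divides each neighbor's contribution by
    (z_bj * d_ib + 1), and the center update solves the Lagrangian
    stationarity condition, mixing each pixel with its neighborhood:

        v_jl = sum_i z_ij^m (x_il + sum_b w_ibj x_bl)
             / sum_i z_ij^m (1   + sum_b w_ibj) ,
        w_ibj = (1 - z_bj)^m / (z_bj d_ib + 1) .
    """

    algorithm = "improved_flicm"

    def _neighbor_u(self, z):
        """(K, N, C) membership-constrained neighbor weights, masked."""
        nb = self.neighborhood
        zg, mask = nb.gather(z)
        zb = np.clip(zg, _MEMBERSHIP_FLOOR, None)
        u = (1.0 - zg) ** self.m / (zb * nb.distances[:, None, None] + 1.0)
        return u * mask[:, :, None]

    def _fuzzy_factor(self, X, z, v):
        if self.neighborhood is None:
            return 0.0
        d2 = _pairwise_sq_dist(X, v)
        d2g, mask = self.neighborhood.gather(d2)
        return (self._neighbor_u(z) * d2g).sum(axis=0)

    def _centers(self, X, z, v_prev):
        if self.neighborhood is None:
            return _fcm_centers(X, z, self.m, v_prev)
        u = self._neighbor_u(z)                       # (K, N, C)
        Xg, _ = self.neighborhood.gather(X)           # (K, N, D)
        A = X[:, None, :] + np.einsum("knc,knd->ncd", u, Xg)  # (N, C, D)
        B = 1.0 + u.sum(axis=0)                       # (N, C)
        zm = z ** self.m
        num = np.einsum("nc,ncd->cd", zm, A)
        den = (zm * B).sum(axis=0)
        v = v_prev.copy()
        ok = den > _MEMBERSHIP_FLOOR
        v[ok] = num[ok] / den[ok, None]
        return v


def flicm_fuzzy_factor(state: FuzzyResults, spec: Neighborhood, i: int, j: int,
                       *, inverse_distance: bool = False) -> float:
    """FLICM fuzzy factor G_ij for one pixel/class, from a fitted state.

    Direct (non-vectorized) evaluation, used to cross-check the array path.
    """
    X = state.image.values
    idx, dist = spec.neighbors(i)
    if not 0 <= j < state.centers.shape[0]:
        raise IndexError(f"class index {j} out of range")
    w = 1.0 / dist if inverse_distance else 1.0 / (dist + 1.0)
    d2 = ((X[idx] - state.centers[j]) ** 2).sum(axis=1)
    return float((w * (1.0 - state.z[idx, j]) ** state.m * d2).sum())


# ---------------------------------------------------------------------------
# Functional wrappers mirroring the class interface.

def fcm(image, C: int, m: float = 2.0, tol: float = 1e-4,
        max_iter: int = 300, seed: int = 0) -> FuzzyResults:
    """Fit plain FCM; see :class:`FCM`."""
    return FCM(image, C, m=m, tol=tol, max_iter=max_iter).fit(seed)


def flicm(image, C: int, m: float = 2.0, tol: float = 1e-4, max_iter: int = 300,
          seed: int = 0, spec: Neighborhood | None = None, *,
          window: int | None = 3, inverse_distance: bool = False) -> FuzzyResults:
    """Fit FLICM; see :class:`FLICM`."""
    model = FLICM(image, C, m=m, tol=tol, max_iter=max_iter, window=window,
                  neighborhood=spec, inverse_distance=inverse_distance)
    return model.fit(seed)


def improved_flicm(image, C: int, m: float = 2.0, tol: float = 1e-4,
                   max_iter: int = 300, seed: int = 0,
                   spec: Neighborhood | None = None, *,
                   window: int | None = 3) -> FuzzyResults:
    """Fit the membership-constrained FLICM; see :class:`MembershipConstrainedFLICM`."""
    model = MembershipConstrainedFLICM(image, C, m=m, tol=tol, max_iter=max_iter,
                                       window=window, neighborhood=spec)
    return model.fit(seed)
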