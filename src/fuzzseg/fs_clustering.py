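"""Feature-saliency local fuzzy clustering with KL regularization.

The main segmenter of this package. Each pixel i carries D intensity
features x_il; each class j has a mean mu_jl, a prior pi_j, and the model
additionally holds a *common background* mean eps_l and a feature weight
rho_l in (0, 1). A saliency variable s_ijl in (0, 1) decides, per pixel,
class and feature, whether feature l behaves class-specifically (drawn to
mu_jl) or like undiscriminating background (drawn to eps_l). Spatial
coherence enters twice:

* every squared distance is augmented by its neighborhood analogue, each
  neighbor b weighted by u_ibj = (1 - z_bj)^m / (z_bj d_ib + 1), so
  neighbors that confidently belong to class j stop penalizing it; and
* the membership update is weighted by H_ij^alpha, where H_ij is the median
  of the neighbors' memberships for class j — a median filter applied to
  the membership field inside the update rather than after it.

The objective combines the saliency-weighted distances with two KL
regularizers, lambda * sum z log(z/pi) pulling memberships toward the class
priors and gamma * sum z KL(s || rho) pulling saliencies toward the feature
priors. All update equations are the exact coordinate-wise stationary
points of this objective (verified numerically in the test suite), giving
closed-form alternating optimization:

    s_ijl = rho_l e^{t/gamma} / (1 - rho_l + rho_l e^{t/gamma}),
    z_ij  = pi_j H_ij^alpha e^{-eta_ij/lambda} / (normalizer),
    mu, eps = neighborhood-consistent weighted means,
    rho_l = mean_i sum_j z_ij s_ijl,    pi_j = mean_i z_ij.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .baselines import FCM, initial_memberships  # noqa: F401  (re-export convenience)
from .image_io import FeatureImage, LabelMap
from .neighborhood import Neighborhood

__all__ = [
    "FSModel",
    "Hyperparameters",
    "FSResults",
    "FeatureSaliencyFLICM",
    "fit",
    "neighbor_weight",
    "saliency_logit",
    "update_saliency",
    "class_cost",
    "median_field",
    "update_membership",
    "membership_softmax",
    "update_model",
    "objective",
    "label",
]

_FLOOR = 1e-12
_RHO_CLIP = 1e-6


@dataclass
class FSModel:
    """Mixture parameters: class means, priors, background means, feature weights."""

    mu: np.ndarray        # (C, D) class means
    pi: np.ndarray        # (C,)  class priors, sum 1
    eps: np.ndarray       # (D,)  common (background) feature means
    rho: np.ndarray       # (D,)  feature saliency priors in (0, 1)
    sigma2: np.ndarray | None = None   # (C, D) class variances, diagnostics only
    nu2: np.ndarray | None = None      # (D,)  background variances, diagnostics only


@dataclass(frozen=True)
class Hyperparameters:
    """Tuning knobs of the segmenter.

    lam (membership-entropy weight) and gamma (feature-selection weight) are
    calibrated against squared 0-255 intensity distances; alpha is the
    exponent on the neighborhood membership median; tol is the max-norm
    membership-change threshold.
    """

    lam: float = 1e3
    gamma: float = 1e3
    alpha: float = 2.0
    m: float = 2.0
    window: int = 3
    tol: float = 1e-4
    max_iter: int = 300
    center_update: str = "lagrangian"   # or "printed": plain weighted mean

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        if self.center_update not in ("lagrangian", "printed"):
            raise ValueError("center_update must be 'lagrangian' or 'printed'")


# ---------------------------------------------------------------------------
# Neighborhood sums

def _neighbor_sums(X, z, nb: Neighborhood, m: float):
    """Weighted neighbor sums S0 = sum_b u, Sx = sum_b u x_b, Sxx = sum_b u x_b^2.

    u_ibj = (1 - z_bj)^m / (z_bj d_ib + 1); shapes (N, C), (N, C, D), (N, C, D).
    """
    zg, mask = nb.gather(z)                       # (K, N, C)
    zb = np.clip(zg, _FLOOR, None)
    u = (1.0 - zg) ** m / (zb * nb.distances[:, None, None] + 1.0)
    u = u * mask[:, :, None]
    Xg, _ = nb.gather(X)                          # (K, N, D)
    S0 = u.sum(axis=0)
    Sx = np.einsum("knc,knd->ncd", u, Xg)
    Sxx = np.einsum("knc,knd->ncd", u, Xg ** 2)
    return S0, Sx, Sxx


def _quad_around(S0, Sx, Sxx, center):
    """sum_b u_ibj (x_bl - c_jl)^2 for per-class centers ``center`` of shape (C, D)."""
    return Sxx - 2.0 * center[None] * Sx + (center ** 2)[None] * S0[..., None]


def neighbor_weight(z, spec: Neighborhood, i: int, beta: int, j: int,
                    m: float = 2.0) -> float:
    """Scalar neighbor weight u_ibj = (1 - z_bj)^m / (z_bj d_ib + 1)."""
    idx, dist = spec.neighbors(i)
    pos = np.where(idx == beta)[0]
    if pos.size == 0:
        raise ValueError(f"pixel {beta} is not a neighbor of pixel {i}")
    d = dist[pos[0]]
    zb = float(z[beta, j])
    return (1.0 - zb) ** m / (max(zb, _FLOOR) * d + 1.0)


# ---------------------------------------------------------------------------
# Closed-form updates

def _logits(X, model: FSModel, S0, Sx, Sxx):
    """t_ijl: background-vs-class evidence for feature l at (pixel i, class j)."""
    C, D = model.mu.shape
    eps_cd = np.broadcast_to(model.eps, (C, D))
    q_eps = (X[:, None, :] - model.eps) ** 2 + _quad_around(S0, Sx, Sxx, eps_cd)
    q_mu = (X[:, None, :] - model.mu[None]) ** 2 + _quad_around(S0, Sx, Sxx, model.mu)
    return q_eps - q_mu


def saliency_logit(image, z, model: FSModel, spec: Neighborhood,
                   i: int, j: int, l: int, m: float = 2.0) -> float:
    """Direct per-entry evaluation of the saliency logit t_ijl."""
    X = _values(image)
    idx, dist = spec.neighbors(i)
    zb = z[idx, j]
    u = (1.0 - zb) ** m / (np.clip(zb, _FLOOR, None) * dist + 1.0)
    xb = X[idx, l]
    x = X[i, l]
    t_eps = (x - model.eps[l]) ** 2 + (u * (xb - model.eps[l]) ** 2).sum()
    t_mu = (x - model.mu[j, l]) ** 2 + (u * (xb - model.mu[j, l]) ** 2).sum()
    return float(t_eps - t_mu)


def update_saliency(image, z, model: FSModel, spec: Neighborhood,
                    gamma: float, m: float = 2.0) -> np.ndarray:
    """Closed-form saliency update: logistic of t/gamma around the prior rho.

    s_ijl = rho_l e^{t/gamma} / (1 - rho_l + rho_l e^{t/gamma}), computed as
    a numerically safe sigmoid of t/gamma + logit(rho_l); clamped away from
    {0, 1} so downstream logarithms stay finite.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    X = _values(image)
    S0, Sx, Sxx = _neighbor_sums(X, z, spec, m)
    t = _logits(X, model, S0, Sx, Sxx)
    rho = np.clip(model.rho, _RHO_CLIP, 1.0 - _RHO_CLIP)
    s = expit(t / gamma + np.log(rho / (1.0 - rho)))
    return np.clip(s, _FLOOR, 1.0 - _FLOOR)


def _costs(X, model: FSModel, s, S0, Sx, Sxx, gamma):
    """eta_ij: saliency-weighted distance plus saliency-KL cost, shape (N, C)."""
    C, D = model.mu.shape
    eps_cd = np.broadcast_to(model.eps, (C, D))
    q_mu = (X[:, None, :] - model.mu[None]) ** 2 + _quad_around(S0, Sx, Sxx, model.mu)
    q_eps = (X[:, None, :] - model.eps) ** 2 + _quad_around(S0, Sx, Sxx, eps_cd)
    rho = np.clip(model.rho, _RHO_CLIP, 1.0 - _RHO_CLIP)
    kl_mu = gamma * np.log(s / rho)
    kl_eps = gamma * np.log((1.0 - s) / (1.0 - rho))
    return (s * (q_mu + kl_mu) + (1.0 - s) * (q_eps + kl_eps)).sum(axis=-1)


def class_cost(image, z, model: FSModel, saliency, spec: Neighborhood,
               gamma: float, i: int, j: int, m: float = 2.0) -> float:
    """Direct evaluation of the membership cost eta_ij for one pixel/class."""
    X = _values(image)
    S0, Sx, Sxx = _neighbor_sums(X, z, spec, m)
    eta = _costs(X, model, saliency, S0, Sx, Sxx, gamma)
    return float(eta[i, j])


def median_field(z, spec: Neighborhood) -> np.ndarray:
    """Per-class median of the neighbors' memberships, H_ij = median{z_bj}.

    The center pixel is excluded; even neighbor counts average the two
    central order statistics. A pixel with no neighbors keeps its own
    membership.
    """
    zg, mask = spec.gather(z)                     # (K, N, C)
    arr = np.where(mask[:, :, None], zg, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        H = np.nanmedian(arr, axis=0)
    empty = spec.neighbor_counts() == 0
    if empty.any():
        H[empty] = z[empty]
    return H


def membership_softmax(pi, H, eta, lam: float, alpha: float) -> np.ndarray:
    """Row-normalized z_ij proportional to pi_j H_ij^alpha e^{-eta_ij/lambda}.

    Evaluated in log space (log-sum-exp) so huge distance costs cannot
    underflow the whole row.
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    logw = (np.log(np.clip(pi, _FLOOR, None))[None, :]
            + alpha * np.log(np.clip(H, _FLOOR, None))
            - eta / lam)
    logw -= logw.max(axis=1, keepdims=True)
    z = np.exp(logw)
    return z / z.sum(axis=1, keepdims=True)


def update_membership(image, z_prev, model: FSModel, saliency, H,
                      spec: Neighborhood, lam: float, gamma: float,
                      alpha: float, m: float = 2.0) -> np.ndarray:
    """Membership update: softmax of priors, median field and class costs.

    Neighbor weights inside eta use the previous iteration's memberships
    ``z_prev``; H is the median field of that same iteration.
    """
    X = _values(image)
    S0, Sx, Sxx = _neighbor_sums(X, z_prev, spec, m)
    eta = _costs(X, model, saliency, S0, Sx, Sxx, gamma)
    return membership_softmax(model.pi, H, eta, lam, alpha)


def update_model(image, z, saliency, spec: Neighborhood,
                 prev: FSModel, m: float = 2.0,
                 center_update: str = "lagrangian") -> FSModel:
    """Closed-form model update given memberships and saliencies.

    mu and eps are neighborhood-consistent weighted means (each pixel enters
    together with its u-weighted neighbors); rho_l averages the saliency
    mass per feature and pi_j the membership mass per class. A class whose
    total saliency-weighted membership vanishes keeps its previous mean.
    With ``center_update="printed"`` mu and eps fall back to plain weighted
    means without the neighbor terms.
    """
    X = _values(image)
    n = X.shape[0]
    s = saliency
    if center_update == "lagrangian":
        S0, Sx, _ = _neighbor_sums(X, z, spec, m)
        A = X[:, None, :] + Sx          # (N, C, D)
        B = 1.0 + S0                    # (N, C)
    else:
        A = np.broadcast_to(X[:, None, :], s.shape)
        B = np.ones(z.shape)

    w_mu = z[:, :, None] * s            # (N, C, D)
    num_mu = np.einsum("ncd,ncd->cd", w_mu, A)
    den_mu = np.einsum("ncd,nc->cd", w_mu, B)
    mu = prev.mu.copy()
    ok = den_mu > _FLOOR
    if not ok.all():
        warnings.warn("degenerate class: keeping previous mean(s)", RuntimeWarning)
    mu[ok] = num_mu[ok] / den_mu[ok]

    w_eps = z[:, :, None] * (1.0 - s)
    num_eps = np.einsum("ncd,ncd->d", w_eps, A)
    den_eps = np.einsum("ncd,nc->d", w_eps, B)
    eps = prev.eps.copy()
    ok_e = den_eps > _FLOOR
    eps[ok_e] = num_eps[ok_e] / den_eps[ok_e]

    rho = np.clip(w_mu.sum(axis=(0, 1)) / n, _RHO_CLIP, 1.0 - _RHO_CLIP)
    pi = z.sum(axis=0) / n
    return FSModel(mu=mu, pi=pi, eps=eps, rho=rho, sigma2=prev.sigma2, nu2=prev.nu2)


def objective(image, z, model: FSModel, saliency, spec: Neighborhood,
              lam: float, gamma: float, m: float = 2.0) -> float:
    """The regularized clustering objective the updates jointly minimize.

    J = sum_ij z_ij (d_ij + G_ij)
      + lam   * sum_ij  z_ij log(z_ij / pi_j)
      + gamma * sum_ijl z_ij [s log(s/rho) + (1-s) log((1-s)/(1-rho))]

    with d_ij the saliency-weighted squared distance of pixel i and G_ij its
    u-weighted neighborhood analogue (both using the center pixel's
    saliency). 0 log 0 is taken as 0.
    """
    X = _values(image)
    S0, Sx, Sxx = _neighbor_sums(X, z, spec, m)
    s = saliency
    C, D = model.mu.shape
    eps_cd = np.broadcast_to(model.eps, (C, D))
    q_mu = (X[:, None, :] - model.mu[None]) ** 2 + _quad_around(S0, Sx, Sxx, model.mu)
    q_eps = (X[:, None, :] - model.eps) ** 2 + _quad_around(S0, Sx, Sxx, eps_cd)
    dist_term = (z * (s * q_mu + (1.0 - s) * q_eps).sum(axis=-1)).sum()

    pi = np.clip(model.pi, _FLOOR, None)
    ent = np.where(z > _FLOOR, z * np.log(np.clip(z, _FLOOR, None) / pi[None]), 0.0).sum()

    rho = np.clip(model.rho, _RHO_CLIP, 1.0 - _RHO_CLIP)
    sc = np.clip(s, _FLOOR, 1.0 - _FLOOR)
    kl = (z[:, :, None] * (sc * np.log(sc / rho)
                           + (1.0 - sc) * np.log((1.0 - sc) / (1.0 - rho)))).sum()
    return float(dist_term + lam * ent + gamma * kl)


# ---------------------------------------------------------------------------
# Model / Results objects

@dataclass
class FSResults:
    """Fitted state of the feature-saliency segmenter."""

    image: FeatureImage
    z: np.ndarray                # (N, C) memberships
    H: np.ndarray                # (N, C) last neighborhood median field
    model: FSModel
    saliency: np.ndarray         # (N, C, D)
    hyper: Hyperparameters
    n_iter: int
    converged: bool
    objective_trace: list[float] = field(default_factory=list)
    algorithm: str = "fs"

    def labels(self) -> np.ndarray:
        return np.argmax(self.z, axis=1)

    def label_map(self) -> LabelMap:
        return LabelMap(self.image.height, self.image.width,
                        self.labels(), self.z.shape[1])

    def summary(self) -> str:
        h = self.hyper
        lines = [
            "Feature-saliency local fuzzy clustering results",
            "=" * 48,
            f"pixels: {self.image.n_pixels}   classes: {self.z.shape[1]}   "
            f"features: {self.image.n_channels}",
            f"lambda={h.lam:g}  gamma={h.gamma:g}  alpha={h.alpha:g}  "
            f"m={h.m:g}  window={h.window}",
            f"iterations: {self.n_iter}   converged: {self.converged}",
            f"final objective: {self.objective_trace[-1]:.6g}"
            if self.objective_trace else "final objective: n/a",
            "class means mu (intensity units):",
        ]
        for j, row in enumerate(self.model.mu):
            lines.append(f"  class {j}: "
                         + ", ".join(f"{x:.2f}" for x in row)
                         + f"   prior pi={self.model.pi[j]:.3f}")
        lines.append("background means eps: "
                     + ", ".join(f"{x:.2f}" for x in self.model.eps))
        lines.append("feature weights rho:  "
                     + ", ".join(f"{x:.3f}" for x in self.model.rho))
        return "\n".join(lines)


class FeatureSaliencyFLICM:
    """Feature-saliency local fuzzy clustering model for an image.

    Parameters
    ----------
    image : FeatureImage or array
        Input image (grayscale D=1 is the reference configuration).
    n_classes : int
        Number of classes C >= 2.
    **hyper
        Any field of :class:`Hyperparameters` (lam, gamma, alpha, m, window,
        tol, max_iter, center_update).
    """

    algorithm = "fs"

    def __init__(self, image, n_classes: int, **hyper):
        self.image = image if isinstance(image, FeatureImage) \
            else FeatureImage.from_array(np.asarray(image))
        if n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        self.n_classes = int(n_classes)
        self.hyper = hyper.pop("hyper", None) or Hyperparameters(**hyper)
        self.neighborhood = Neighborhood(self.image.height, self.image.width,
                                         self.hyper.window)

    def _initialize(self, seed: int):
        """FCM warm start: class means/variances plus the common background stats."""
        X = self.image.values
        h = self.hyper
        res = FCM(self.image, self.n_classes, m=h.m, tol=h.tol,
                  max_iter=h.max_iter).fit(seed)
        z = res.z
        weights = np.clip(z.sum(axis=0), _FLOOR, None)
        sigma2 = np.einsum("nc,ncd->cd", z,
                           (X[:, None, :] - res.centers[None]) ** 2) / weights[:, None]
        model = FSModel(
            mu=res.centers.copy(),
            pi=np.full(self.n_classes, 1.0 / self.n_classes),
            eps=X.mean(axis=0),
            rho=np.full(self.image.n_channels, 1.0 / self.image.n_channels),
            sigma2=sigma2,
            nu2=X.var(axis=0),
        )
        return z, model

    def fit(self, seed: int = 0) -> FSResults:
        """Run the full alternating schedule until the membership field settles."""
        h = self.hyper
        nb = self.neighborhood
        img = self.image
        z, model = self._initialize(seed)
        trace: list[float] = []
        converged = False
        it = 0
        H = z
        s = np.broadcast_to(model.rho, z.shape + (img.n_channels,)).copy()
        for it in range(1, h.max_iter + 1):
            H = median_field(z, nb)
            s = update_saliency(img, z, model, nb, h.gamma, h.m)
            z_new = update_membership(img, z, model, s, H, nb, h.lam,
                                      h.gamma, h.alpha, h.m)
            model = update_model(img, z_new, s, nb, model, h.m, h.center_update)
            trace.append(objective(img, z_new, model, s, nb, h.lam, h.gamma, h.m))
            delta = np.abs(z_new - z).max()
            z = z_new
            if delta < h.tol:
                converged = True
                break
        return FSResults(img, z, H, model, s, h, it, converged, trace)


def fit(image, C: int, *, lam: float = 1e3, gamma: float = 1e3,
        alpha: float = 2.0, m: float = 2.0, window: int = 3,
        tol: float = 1e-4, max_iter: int = 300, seed: int = 0,
        center_update: str = "lagrangian") -> FSResults:
    """Fit the feature-saliency segmenter; see :class:`FeatureSaliencyFLICM`."""
    model = FeatureSaliencyFLICM(image, C, lam=lam, gamma=gamma, alpha=alpha,
                                 m=m, window=window, tol=tol, max_iter=max_iter,
                                 center_update=center_update)
    return model.fit(seed)


def label(state: FSResults) -> LabelMap:
    """Max-membership labeling of a fitted state (lowest index wins ties)."""
    return state.label_map()


def _values(image) -> np.ndarray:
    if isinstance(image, FeatureImage):
        return image.values
    arr = np.asarray(image, dtype=float)
    return arr[:, None] if arr.ndim == 1 else arr
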