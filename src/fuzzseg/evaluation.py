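"""Segmentation scoring: misclassification rate and peak signal-to-noise ratio.

Clustering emits arbitrary label identities, so the misclassification rate
(MCR) is computed after choosing the label permutation that maximizes
agreement with the ground truth — exhaustively for up to 6 classes, by
optimal assignment (Hungarian) beyond. PSNR for segmentation quality is
measured between the clean reference and the class-mean reconstruction of
the predicted labels, i.e. how well the predicted partition explains the
clean image.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .image_io import FeatureImage, LabelMap, class_mean_reconstruction
from .noise_synth import Phantom

__all__ = ["SegScore", "mcr", "matched_permutation", "psnr", "score_segmentation"]

_EXHAUSTIVE_MAX = 6


@dataclass(frozen=True)
class SegScore:
    """MCR (percent), PSNR (dB; inf for an exact reconstruction) and the
    label permutation used to align prediction with truth."""

    mcr: float
    psnr: float
    matched_permutation: tuple[int, ...]


def _contingency(pred: LabelMap, truth: LabelMap) -> np.ndarray:
    if (pred.height, pred.width) != (truth.height, truth.width):
        raise ValueError("prediction and truth shapes disagree")
    c = max(pred.n_classes, truth.n_classes)
    table = np.zeros((c, c), dtype=np.int64)
    np.add.at(table, (pred.labels, truth.labels), 1)
    return table


def _best_permutation(table: np.ndarray, method: str) -> tuple[int, ...]:
    """Permutation p (pred class k -> truth class p[k]) maximizing agreement."""
    c = table.shape[0]
    if method == "auto":
        method = "exhaustive" if c <= _EXHAUSTIVE_MAX else "assignment"
    if method == "exhaustive":
        best, best_perm = -1, tuple(range(c))
        for perm in itertools.permutations(range(c)):
            agree = sum(table[k, perm[k]] for k in range(c))
            if agree > best:
                best, best_perm = agree, perm
        return best_perm
    if method == "assignment":
        rows, cols = linear_sum_assignment(table, maximize=True)
        perm = np.empty(c, dtype=int)
        perm[rows] = cols
        return tuple(perm)
    raise ValueError(f"unknown matching method {method!r}")


def mcr(pred: LabelMap, truth: LabelMap, method: str = "auto") -> float:
    """Misclassification rate in percent, after optimal label matching.

    MCR = [1 - N^{-1} sum_j |A_j ∩ C_j|] x 100 over the best relabeling of
    the prediction; 0 for a perfect (up to relabeling) segmentation.
    """
    table = _contingency(pred, truth)
    perm = _best_permutation(table, method)
    agree = sum(table[k, perm[k]] for k in range(table.shape[0]))
    return float((1.0 - agree / truth.labels.size) * 100.0)


def matched_permutation(pred: LabelMap, truth: LabelMap,
                        method: str = "auto") -> tuple[int, ...]:
    """The label permutation mcr() used to align *pred* with *truth*."""
    return _best_permutation(_contingency(pred, truth), method)


def psnr(reference: FeatureImage, test: FeatureImage, peak: float = 255.0) -> float:
    """10 log10(peak^2 / MSE) in dB; ``inf`` for identical images."""
    if (reference.height, reference.width) != (test.height, test.width) \
            or reference.n_channels != test.n_channels:
        raise ValueError("reference and test image shapes disagree")
    if peak <= 0:
        raise ValueError("peak must be positive")
    mse = float(((reference.values - test.values) ** 2).mean())
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(peak * peak / mse)


def score_segmentation(phantom: Phantom, pred: LabelMap) -> SegScore:
    """Score a predicted segmentation of a phantom.

    MCR against the ground-truth labels; PSNR between the clean image and
    its class-mean reconstruction under the predicted labels.
    """
    table = _contingency(pred, phantom.truth)
    perm = _best_permutation(table, "auto")
    agree = sum(table[k, perm[k]] for k in range(table.shape[0]))
    rate = float((1.0 - agree / phantom.truth.labels.size) * 100.0)
    recon = class_mean_reconstruction(phantom.image, pred)
    peak = phantom.image.intensity_range[1]
    return SegScore(rate, psnr(phantom.image, recon, peak=peak), perm)
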