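"""Shared fixtures: random instances and the numeric-gradient oracle."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from fuzzseg import FeatureImage, Neighborhood
from fuzzseg import fs_clustering as fsc

# Intensity scale for stationarity instances: small enough that the saliency
# logistic never saturates (its clamp would turn interior stationary points
# into boundary ones), large enough that all terms are exercised.
ORACLE_SCALE = 30.0
LAM = 1e3
GAMMA = 1e3


def random_instance(rng, scale=ORACLE_SCALE):
    """A random small clustering state: image, neighborhood, memberships, model."""
    h, w = int(rng.integers(2, 5)), int(rng.integers(2, 5))
    C, D = int(rng.integers(2, 4)), int(rng.integers(1, 3))
    img = FeatureImage.from_array(rng.uniform(0, scale, (h, w, D)),
                                  intensity_range=(0.0, scale))
    nb = Neighborhood(h, w, 3)
    z = rng.random((h * w, C))
    z /= z.sum(axis=1, keepdims=True)
    model = fsc.FSModel(
        mu=rng.uniform(0, scale, (C, D)),
        pi=rng.dirichlet(np.ones(C)),
        eps=rng.uniform(0, scale, D),
        rho=rng.uniform(0.1, 0.9, D),
    )
    return img, nb, z, model


def numeric_partial(objective_fn, model, attr, index, step):
    """Central-difference partial of objective_fn w.r.t. one model entry."""
    arr = getattr(model, attr)
    up, down = arr.copy(), arr.copy()
    up[index] += step
    down[index] -= step
    return (objective_fn(dataclasses.replace(model, **{attr: up}))
            - objective_fn(dataclasses.replace(model, **{attr: down}))) / (2 * step)


@pytest.fixture
def rng():
    return np.random.default_rng(20240417)


@pytest.fixture
def small_image():
    """A deterministic 4x4 two-feature image."""
    gen = np.random.default_rng(7)
    return FeatureImage.from_array(gen.uniform(0, 255, (4, 4, 2)))
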