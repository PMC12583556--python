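"""Shared fixtures.

The two trained models are expensive (minutes each), so they are built
once per session and shared between the unit/property tests and the
acceptance tests. Training conditions mirror the study conditions of
the scaled-down reproductions documented in docs/methods.md.
"""

from __future__ import annotations

import numpy as np
import pytest

from miro.datasets import (AugmentConfig, extract_clusters, make_training_set,
                           simulate_arc_clusters)
from miro.estimators import MiroTransformer


@pytest.fixture(scope="session")
def gaussian_sources():
    """Representative 25 nm Gaussian clusters (15 localizations each)."""
    rng = np.random.default_rng(0)
    return [rng.normal(0.0, 25.0, (15, 2)) for _ in range(5)]


@pytest.fixture(scope="session")
def gaussian_training_fovs(gaussian_sources):
    return make_training_set(
        gaussian_sources,
        AugmentConfig(n_pointclouds=150, fov_size=1000.0, clusters_per_fov=(3, 6),
                      background_fraction=0.3, jitter_sd=2.0, seed=1),
    )


@pytest.fixture(scope="session")
def gaussian_model(gaussian_training_fovs):
    """Model trained to collapse 25 nm Gaussian clusters."""
    est = MiroTransformer(hidden_dim=64, n_steps=10, epochs=40, delta=80.0,
                          learning_rate=3e-3, random_state=0)
    est.fit(gaussian_training_fovs)
    return est


@pytest.fixture(scope="session")
def gaussian_test_fovs(gaussian_sources):
    """Held-out FOVs from the same cluster distribution."""
    return make_training_set(
        gaussian_sources,
        AugmentConfig(n_pointclouds=10, fov_size=1000.0, clusters_per_fov=(3, 6),
                      background_fraction=0.3, jitter_sd=2.0, seed=99),
    )


@pytest.fixture(scope="session")
def cshape_model():
    """Scaled-down model trained on C-shaped clusters via augmentation.

    Few-shot protocol: one labeled FOV supplies the source clusters;
    200 augmented training FOVs; H=64, K=10, 30 epochs.
    """
    source = simulate_arc_clusters("c_shape", seed=100)
    sources = extract_clusters(source)
    training = make_training_set(
        sources,
        AugmentConfig(n_pointclouds=200, fov_size=1600.0, clusters_per_fov=(1, 3),
                      background_fraction=0.06, jitter_sd=2.0, seed=1),
    )
    est = MiroTransformer(hidden_dim=64, n_steps=10, epochs=30, delta=250.0,
                          feature_scale=50.0, alpha=1.0, learning_rate=3e-3,
                          random_state=0)
    est.fit(training)
    return est


@pytest.fixture(scope="session")
def cshape_test_fovs():
    return [simulate_arc_clusters("c_shape", seed=200 + i) for i in range(10)]
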