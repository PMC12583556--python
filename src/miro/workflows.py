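"""End-to-end workflows shared by the CLI, scripts and tests.

These functions tie the generators, training, clustering and metrics
together: train a model from a few labeled FOVs via augmentation, and
benchmark DBSCAN alone against the squeeze-then-DBSCAN pipeline on a
simulated scenario.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cluster import dbscan, optimize_dbscan_params, _compact
from .datasets import AugmentConfig, extract_clusters
from .estimators import MiroTransformer
from .metrics import evaluate

__all__ = ["train_few_shot", "benchmark_scenario"]


def train_few_shot(source_fovs, transformer: MiroTransformer,
                   augment: AugmentConfig) -> MiroTransformer:
    """Train from a few labeled FOVs through the augmentation pipeline.

    Clusters are extracted from ``source_fovs`` (labeled tables), turned
    into ``augment.n_pointclouds`` synthetic training FOVs, and the
    transformer is fitted on those.
    """
    sources = []
    for fov in source_fovs:
        sources.extend(extract_clusters(fov))
    if not sources:
        raise ValueError("no clusters found in the source FOVs")
    from .datasets import make_training_set
    training = make_training_set(sources, augment)
    return transformer.fit(training)


def benchmark_scenario(test_fovs, transformer: MiroTransformer,
                       grid=None, optimize_fovs: int = 8,
                       xi: float | None = None) -> pd.DataFrame:
    """Compare DBSCAN alone with the squeeze-then-DBSCAN pipeline.

    Both methods get their own grid-optimized (eps, min_samples) pair,
    selected on the first ``optimize_fovs`` test FOVs by mean ARI, then
    applied uniformly. Returns a tidy DataFrame with one row per
    (FOV, method) holding the full metric panel.
    """
    coords = [f[["x", "y"]].to_numpy(float) for f in test_fovs]
    labels = [f["label"].to_numpy(int) for f in test_fovs]
    squeezed = [transformer.transform(c) for c in coords]

    k = min(optimize_fovs, len(test_fovs))
    eps_raw, ms_raw = optimize_dbscan_params(coords[:k], labels[:k], grid)
    eps_sq, ms_sq = optimize_dbscan_params(squeezed[:k], labels[:k], grid)

    rows = []
    for i, (c, sq, y) in enumerate(zip(coords, squeezed, labels)):
        for method, pts, (eps, ms) in (("dbscan", c, (eps_raw, ms_raw)),
                                       ("miro", sq, (eps_sq, ms_sq))):
            pred = _compact(dbscan(pts, eps, ms))
            rep = evaluate(y, pred, coords=c, xi=xi)
            rows.append({"fov": i, "method": method, "eps": eps,
                         "min_samples": ms, **rep})
    return pd.DataFrame(rows)
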