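"""Post-processing: displacement application, DBSCAN, parameter search.

The trained network supplies a displacement field; adding it to the
coordinates squeezes cluster members toward common centers, after which
ordinary DBSCAN separates them. One (eps, min_samples) pair is selected
per scenario by maximizing a partition metric (ARI by default) averaged
over labeled fields of view, and the same pair is applied uniformly to
every FOV of that scenario. Cluster identity transfers back to the
original coordinates by row index: all reported centroids and metrics
refer to the unsqueezed positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from sklearn.cluster import DBSCAN

from . import metrics as _metrics
from .graph import GraphConfig, build_graph
from .network import forward

__all__ = [
    "ClusterResult",
    "apply_displacements",
    "dbscan",
    "default_grid",
    "optimize_dbscan_params",
    "classify_clusters",
    "miro_pipeline",
]


@dataclass
class ClusterResult:
    """Final clustering of one field of view.

    ``labels`` are compacted to 0..n_clusters-1 with -1 for noise;
    ``cluster_classes`` optionally maps cluster id -> structural class.
    """

    labels: np.ndarray
    eps: float
    min_samples: int
    cluster_classes: dict | None = None
    squeezed: np.ndarray | None = None

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max() + 1) if (self.labels >= 0).any() else 0


def apply_displacements(coords, step_outputs) -> np.ndarray:
    """Add the final-step displacement field to the coordinates.

    ``step_outputs`` may be the dict returned by the network forward
    pass, a list of per-step displacement arrays, or a single array.
    """
    coords = np.asarray(coords, float)
    if isinstance(step_outputs, dict):
        disp = step_outputs["r"][-1]
    elif isinstance(step_outputs, (list, tuple)):
        disp = step_outputs[-1]
    else:
        disp = step_outputs
    return coords + np.asarray(disp, float)


def _compact(labels: np.ndarray) -> np.ndarray:
    out = np.full(len(labels), -1, dtype=int)
    ids = [l for l in np.unique(labels) if l >= 0]
    for new, old in enumerate(sorted(ids)):
        out[labels == old] = new
    return out


def dbscan(coords, eps: float, min_samples: int) -> np.ndarray:
    """Density-based clustering with standard semantics.

    A point is a core point when at least ``min_samples`` points
    (itself included) lie within ``eps``; density-reachable points share
    a label and everything else is noise (-1).
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    coords = np.asarray(coords, float)
    if len(coords) == 0:
        return np.empty(0, dtype=int)
    return DBSCAN(eps=eps, min_samples=min_samples).fit(coords).labels_


def default_grid(eps_range=(10.0, 100.0, 5.0), min_samples_range=(3, 30, 1)):
    """The default (eps, min_samples) search grid (nm; start, stop, step)."""
    e0, e1, es = eps_range
    m0, m1, ms = min_samples_range
    eps_vals = np.arange(e0, e1 + es / 2, es)
    ms_vals = range(int(m0), int(m1) + 1, int(ms))
    return [(float(e), int(m)) for e, m in product(eps_vals, ms_vals)]


def optimize_dbscan_params(fovs, gt_labels, grid=None, objective: str = "ari"):
    """Pick one (eps, min_samples) pair for a whole scenario.

    Exhaustively scans the grid and returns the pair maximizing the mean
    objective (``ari`` by default, any key of the metric panel that
    needs no coordinates) across the labeled FOVs. Ties break toward
    the smallest eps, then the smallest min_samples.

    Parameters
    ----------
    fovs : list of (n_i, 2) coordinate arrays
    gt_labels : list of matching ground-truth label arrays
    grid : list of (eps, min_samples) pairs, optional
    """
    if len(fovs) == 0 or len(fovs) != len(gt_labels):
        raise ValueError("need equally many FOVs and label arrays")
    grid = default_grid() if grid is None else list(grid)
    if not grid:
        raise ValueError("empty parameter grid")
    score_fn = {"ari": _metrics.ari, "ami": _metrics.ami}.get(objective)
    if score_fn is None:
        raise ValueError(f"unsupported objective {objective!r}")
    best = None
    for eps, ms in sorted(grid):
        scores = [score_fn(y, dbscan(X, eps, ms)) for X, y in zip(fovs, gt_labels)]
        mean = float(np.mean(scores))
        if best is None or mean > best[0]:
            best = (mean, eps, ms)
    return best[1], best[2]


def classify_clusters(labels, node_class_logits) -> dict[int, int]:
    """Per-cluster structural class: mode of member node predictions.

    Node predictions are argmaxes of ``node_class_logits`` (class 0 is
    background); ties break toward the lower class id.
    """
    labels = np.asarray(labels, int)
    preds = np.argmax(np.asarray(node_class_logits, float), axis=1)
    out = {}
    for lab in np.unique(labels):
        if lab < 0:
            continue
        votes = np.bincount(preds[labels == lab])
        out[int(lab)] = int(votes.argmax())
    return out


def miro_pipeline(table, params, model_cfg, graph_cfg: GraphConfig,
                  eps: float, min_samples: int) -> ClusterResult:
    """Full workflow: graph -> network -> squeeze -> DBSCAN [-> classify].

    ``table`` is a localization table (or (N, 2) array). Labels are
    reported against the original coordinates.
    """
    coords = (table[["x", "y"]].to_numpy(float) if hasattr(table, "columns")
              else np.asarray(table, float).reshape(-1, 2))
    if len(coords) == 0:
        return ClusterResult(labels=np.empty(0, int), eps=eps, min_samples=min_samples,
                             squeezed=coords.copy())
    graph = build_graph(coords, graph_cfg)
    out = forward(graph, params, model_cfg)
    squeezed = apply_displacements(coords, out)
    labels = _compact(dbscan(squeezed, eps, min_samples))
    classes = None
    if model_cfg.n_classes:
        classes = classify_clusters(labels, out["logits"][-1])
    return ClusterResult(labels=labels, eps=eps, min_samples=min_samples,
                         cluster_classes=classes, squeezed=squeezed)
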