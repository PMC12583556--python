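"""Scikit-learn style estimators.

:class:`MiroTransformer` learns the displacement field from labeled
fields of view and squeezes new point clouds (``fit`` / ``transform``);
:class:`MiroDBSCAN` chains it with DBSCAN and a scenario-wide parameter
search into an inductive clusterer (``fit`` on labeled FOVs,
``predict`` cluster labels for new ones). Both follow the scikit-learn
parameter conventions (``get_params`` / ``set_params``, fitted
attributes with a trailing underscore), so they compose with pipelines
and model selection; the functional modules remain available underneath.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin

from .cluster import (ClusterResult, apply_displacements, classify_clusters,
                      dbscan, default_grid, optimize_dbscan_params, _compact)
from .graph import GraphConfig, build_graph, suggest_delta
from .network import ModelConfig, count_parameters, forward
from .objective import TrainingConfig, displacement_targets, train

__all__ = ["MiroTransformer", "MiroDBSCAN"]


def _as_coords(X) -> np.ndarray:
    if hasattr(X, "columns"):
        return X[["x", "y"]].to_numpy(float)
    return np.asarray(X, float).reshape(-1, 2)


def _as_fov_list(X, y=None):
    """Normalize input into a list of labeled DataFrames."""
    if isinstance(X, pd.DataFrame):
        X = [X]
    elif isinstance(X, np.ndarray) and X.ndim == 2:
        X = [X]
    fovs = []
    for i, item in enumerate(X):
        if isinstance(item, pd.DataFrame):
            fovs.append(item)
        else:
            coords = np.asarray(item, float).reshape(-1, 2)
            df = pd.DataFrame(coords, columns=["x", "y"])
            if y is not None:
                labels = np.asarray(y[i], int)
                if labels.ndim == 2:
                    df["sublabel"] = labels[:, 0]
                    df["label"] = labels[:, 1]
                else:
                    df["label"] = labels
            fovs.append(df)
    return fovs


class MiroTransformer(TransformerMixin, BaseEstimator):
    """Learnable point-cloud squeezer.

    Parameters
    ----------
    hidden_dim, n_steps, n_eig, n_classes, k_star : int
        Architecture settings (see :class:`miro.network.ModelConfig`).
    delta : float or None
        Delaunay edge-length threshold in nm; ``None`` derives it from
        the training data as the ``delta_quantile``-th percentile of
        Delaunay edge lengths.
    delta_quantile : float
    feature_scale : float or None
        Edge-feature normalizer; ``None`` means "use delta".
    alpha, beta : float
        Loss-term weights.
    epochs, learning_rate : training settings.
    random_state : int
        Root seed for initialization and shuffling.

    Attributes
    ----------
    params_ : dict of weight arrays
    delta_, feature_scale_ : resolved graph settings (nm)
    model_config_ : ModelConfig
    history_ : per-epoch loss DataFrame
    n_parameters_ : number of learnable scalars
    """

    def __init__(self, hidden_dim=256, n_steps=15, n_eig=5, n_classes=0,
                 k_star=0, delta=None, delta_quantile=95.0, feature_scale=None,
                 alpha=5.0, beta=0.2, epochs=50, learning_rate=1e-3,
                 random_state=0, verbose=False):
        self.hidden_dim = hidden_dim
        self.n_steps = n_steps
        self.n_eig = n_eig
        self.n_classes = n_classes
        self.k_star = k_star
        self.delta = delta
        self.delta_quantile = delta_quantile
        self.feature_scale = feature_scale
        self.alpha = alpha
        self.beta = beta
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.random_state = random_state
        self.verbose = verbose

    # -- fitting -----------------------------------------------------------
    def _graph_config(self) -> GraphConfig:
        return GraphConfig(delta=self.delta_, n_eig=self.n_eig,
                           feature_scale=self.feature_scale_)

    def fit(self, X, y=None, holdout=None):
        """Train on labeled fields of view.

        ``X`` is a list of localization DataFrames carrying ``label``
        (and ``sublabel`` for multiscale, ``shape_class`` for
        classification) columns, or a list of (n, 2) arrays with ``y``
        a matching list of label vectors.
        """
        fovs = _as_fov_list(X, y)
        if not fovs:
            raise ValueError("no training FOVs")
        if self.delta is not None:
            self.delta_ = float(self.delta)
        else:
            sample = fovs[: min(len(fovs), 10)]
            self.delta_ = float(np.median([
                suggest_delta(_as_coords(f), self.delta_quantile) for f in sample]))
        self.feature_scale_ = float(self.feature_scale
                                    if self.feature_scale is not None else self.delta_)
        self.model_config_ = ModelConfig(
            hidden_dim=self.hidden_dim, n_steps=self.n_steps, n_eig=self.n_eig,
            n_classes=self.n_classes, k_star=self.k_star, seed=self.random_state)
        gcfg = self._graph_config()
        dataset = []
        for f in fovs:
            graph = build_graph(f, gcfg)
            targets = displacement_targets(f, k_star=self.k_star,
                                           n_steps=self.n_steps,
                                           n_classes=self.n_classes)
            dataset.append((graph, targets))
        tcfg = TrainingConfig(alpha=self.alpha, beta=self.beta, epochs=self.epochs,
                              learning_rate=self.learning_rate, seed=self.random_state)
        ho = None
        if holdout is not None:
            hf = _as_fov_list([holdout])[0]
            ho = (build_graph(hf, gcfg), hf["label"].to_numpy(int))
        self.params_, self.history_ = train(dataset, self.model_config_, tcfg,
                                            holdout=ho, verbose=self.verbose)
        self.n_parameters_ = count_parameters(self.params_)
        return self

    # -- inference ---------------------------------------------------------
    def _forward(self, X):
        coords = _as_coords(X)
        graph = build_graph(coords, self._graph_config())
        return coords, graph, forward(graph, self.params_, self.model_config_)

    def predict_displacements(self, X) -> np.ndarray:
        """Final-step displacement field (nm) for one field of view."""
        _, _, out = self._forward(X)
        return out["r"][-1]

    def transform(self, X) -> np.ndarray:
        """Squeezed coordinates for one field of view (or a list of them)."""
        if isinstance(X, (list, tuple)):
            return [self.transform(x) for x in X]
        coords, _, out = self._forward(X)
        return apply_displacements(coords, out)

    def predict_classes(self, X) -> np.ndarray:
        """Per-node class predictions (argmax of final-step logits)."""
        if not self.n_classes:
            raise ValueError("model was configured without class outputs")
        _, _, out = self._forward(X)
        return np.argmax(out["logits"][-1], axis=1)

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        """Save weights and configuration to a checkpoint archive."""
        from .network import save_checkpoint
        save_checkpoint(path, self.params_, self.model_config_,
                        {"delta": self.delta_, "feature_scale": self.feature_scale_,
                         "n_eig": self.n_eig})

    @classmethod
    def load(cls, path) -> "MiroTransformer":
        """Restore a fitted transformer from a checkpoint archive."""
        from .network import load_checkpoint
        params, mcfg, gmeta = load_checkpoint(path)
        est = cls(hidden_dim=mcfg.hidden_dim, n_steps=mcfg.n_steps,
                  n_eig=mcfg.n_eig, n_classes=mcfg.n_classes, k_star=mcfg.k_star,
                  delta=gmeta.get("delta"), feature_scale=gmeta.get("feature_scale"),
                  random_state=mcfg.seed)
        est.params_ = params
        est.model_config_ = mcfg
        est.delta_ = float(gmeta["delta"])
        est.feature_scale_ = float(gmeta.get("feature_scale") or est.delta_)
        est.n_parameters_ = count_parameters(params)
        return est


class MiroDBSCAN(ClusterMixin, BaseEstimator):
    """Squeeze-then-cluster pipeline with scenario-wide DBSCAN parameters.

    ``fit`` trains the transformer (unless one is supplied already
    fitted) and, when ``eps``/``min_samples`` are not given, selects
    them by maximizing mean ARI of DBSCAN on the squeezed training FOVs
    over a grid. ``predict`` clusters a new field of view; labels refer
    to the original coordinates.
    """

    def __init__(self, transformer=None, eps=None, min_samples=None,
                 param_grid=None, optimize_fovs=8, **transformer_params):
        self.transformer = transformer
        self.eps = eps
        self.min_samples = min_samples
        self.param_grid = param_grid
        self.optimize_fovs = optimize_fovs
        self.transformer_params = transformer_params

    def fit(self, X, y=None):
        if self.transformer is not None and hasattr(self.transformer, "params_"):
            self.transformer_ = self.transformer
        else:
            self.transformer_ = (self.transformer or
                                 MiroTransformer(**self.transformer_params))
            self.transformer_.fit(X, y)
        if self.eps is not None and self.min_samples is not None:
            self.eps_, self.min_samples_ = float(self.eps), int(self.min_samples)
            return self
        fovs = _as_fov_list(X, y)[: self.optimize_fovs]
        squeezed = [self.transformer_.transform(f) for f in fovs]
        labels = [f["label"].to_numpy(int) for f in fovs]
        grid = self.param_grid or default_grid()
        self.eps_, self.min_samples_ = optimize_dbscan_params(squeezed, labels, grid)
        return self

    def predict(self, X) -> np.ndarray:
        """Cluster labels for one field of view (-1 = noise)."""
        return self.cluster(X).labels

    def cluster(self, X) -> ClusterResult:
        """Full result for one field of view, including shape classes."""
        coords = _as_coords(X)
        tr = self.transformer_
        if len(coords) == 0:
            return ClusterResult(labels=np.empty(0, int), eps=self.eps_,
                                 min_samples=self.min_samples_, squeezed=coords)
        _, _, out = tr._forward(coords)
        squeezed = apply_displacements(coords, out)
        labels = _compact(dbscan(squeezed, self.eps_, self.min_samples_))
        classes = None
        if tr.model_config_.n_classes:
            classes = classify_clusters(labels, out["logits"][-1])
        return ClusterResult(labels=labels, eps=self.eps_,
                             min_samples=self.min_samples_,
                             cluster_classes=classes, squeezed=squeezed)

    def fit_predict(self, X, y=None):
        self.fit(X, y)
        fovs = _as_fov_list(X, y)
        return [self.predict(f) for f in fovs]
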