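"""Graph representation of a localization point cloud.

Nodes are individual localizations; edges come from a Delaunay
triangulation filtered by a length threshold delta, emitted in both
directions. Absolute coordinates never enter the features: nodes carry
the absolute entries of the smallest non-trivial eigenvectors of the
symmetric normalized graph Laplacian (structural positional encoding),
and each directed edge carries its Euclidean length and the direction
vector ``d_ij = x_j - x_i``, normalized by a feature scale. The result
is invariant to translations of the input by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.linalg
from scipy.spatial import Delaunay, QhullError, cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "GraphConfig",
    "PointGraph",
    "delaunay_filtered_edges",
    "laplacian_embeddings",
    "edge_feature_vectors",
    "build_graph",
    "save_graph",
    "load_graph",
    "suggest_delta",
]

#: eigenvalues below this fraction of the largest one count as zero
_ZERO_EIG_RTOL = 1e-8


@dataclass
class GraphConfig:
    """Graph-construction parameters.

    delta : edge-length threshold in nm (Delaunay edges longer than this
        are dropped).
    n_eig : number of non-trivial Laplacian eigenvectors used as node
        features (default 5).
    feature_scale : distance normalizer for edge features in nm;
        ``None`` means "use delta", keeping edge features O(1) across
        datasets of different density.
    """

    delta: float
    n_eig: int = 5
    feature_scale: float | None = None

    def __post_init__(self):
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.n_eig < 1:
            raise ValueError("n_eig must be >= 1")
        if self.feature_scale is not None and self.feature_scale <= 0:
            raise ValueError("feature_scale must be positive")

    @property
    def scale(self) -> float:
        return self.delta if self.feature_scale is None else self.feature_scale


@dataclass
class PointGraph:
    """A localization graph ready for the network.

    ``edges`` is a (E, 2) int array of directed edges closed under
    orientation reversal; ``node_features`` is (N, n_eig) with
    non-negative entries; ``edge_features`` is (E, 3) holding
    (distance, dx, dy) / feature_scale. ``coords`` (nm) are retained for
    target construction and decoding but are never used as features.
    """

    coords: np.ndarray
    edges: np.ndarray
    node_features: np.ndarray
    edge_features: np.ndarray
    feature_scale: float

    @property
    def n_nodes(self) -> int:
        return len(self.coords)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def delaunay_filtered_edges(coords: np.ndarray, delta: float) -> np.ndarray:
    """Directed edge list from a delta-filtered Delaunay triangulation.

    Returns a (E, 2) array containing both orientations of every
    undirected Delaunay edge not longer than ``delta``. Degenerate
    inputs (< 3 points, or all points collinear) fall back to mutual
    k-nearest-neighbor edges (k=2) with the same filter.
    """
    coords = np.asarray(coords, float)
    n = len(coords)
    if n < 2:
        return np.empty((0, 2), dtype=int)
    pairs = None
    if n >= 3:
        try:
            tri = Delaunay(coords)
            s = tri.simplices
            und = np.vstack([s[:, [0, 1]], s[:, [1, 2]], s[:, [0, 2]]])
            und = np.unique(np.sort(und, axis=1), axis=0)
            pairs = und
        except QhullError:
            logger.warning("degenerate point set; falling back to kNN edges (k=2)")
    if pairs is None:
        k = min(2, n - 1)
        tree = cKDTree(coords)
        _, nbr = tree.query(coords, k=k + 1)
        src = np.repeat(np.arange(n), k)
        dst = nbr[:, 1:].ravel()
        und = np.unique(np.sort(np.column_stack([src, dst]), axis=1), axis=0)
        pairs = und
    lengths = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    pairs = pairs[lengths <= delta]
    if len(pairs) == 0:
        return np.empty((0, 2), dtype=int)
    return np.vstack([pairs, pairs[:, ::-1]]).astype(int)


def _connected_components(n: int, edges: np.ndarray) -> np.ndarray:
    if len(edges) == 0:
        return np.arange(n)
    adj = scipy.sparse.csr_matrix(
        (np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(n, n)
    )
    _, comp = scipy.sparse.csgraph.connected_components(adj, directed=False)
    return comp


def laplacian_embeddings(edges: np.ndarray, n_nodes: int, n_eig: int = 5) -> np.ndarray:
    """Laplacian positional node features.

    For each connected component, the symmetric normalized Laplacian
    ``I - D^{-1/2} A D^{-1/2}`` is eigendecomposed, the (numerically)
    zero eigenvalue of the component is skipped, and the absolute
    entries of the next ``n_eig`` eigenvectors (eigenvalues ascending)
    form the feature rows of the component's nodes, zero-padded when the
    component has fewer non-trivial eigenvectors. Isolated nodes are
    their own components and receive all-zero rows.
    """
    edges = np.asarray(edges, int).reshape(-1, 2)
    feats = np.zeros((n_nodes, n_eig))
    if n_nodes == 0:
        return feats
    comp = _connected_components(n_nodes, edges)
    for c in np.unique(comp):
        nodes = np.flatnonzero(comp == c)
        if len(nodes) < 2:
            continue
        remap = -np.ones(n_nodes, dtype=int)
        remap[nodes] = np.arange(len(nodes))
        mask = (comp[edges[:, 0]] == c) if len(edges) else np.zeros(0, bool)
        sub = remap[edges[mask]]
        m = len(nodes)
        A = np.zeros((m, m))
        A[sub[:, 0], sub[:, 1]] = 1.0
        deg = A.sum(1)
        dinv = 1.0 / np.sqrt(np.maximum(deg, 1e-300))
        L = np.eye(m) - (dinv[:, None] * A) * dinv[None, :]
        L = (L + L.T) / 2.0
        w, v = scipy.linalg.eigh(L)
        tol = _ZERO_EIG_RTOL * max(abs(w[-1]), 1.0)
        nontrivial = np.flatnonzero(np.abs(w) > tol)
        take = nontrivial[:n_eig]
        feats[nodes, : len(take)] = np.abs(v[:, take])
    return feats


def edge_feature_vectors(coords: np.ndarray, edges: np.ndarray,
                         feature_scale: float) -> np.ndarray:
    """Per-edge features (||d_ij||, d_ij_x, d_ij_y) / feature_scale."""
    coords = np.asarray(coords, float)
    edges = np.asarray(edges, int).reshape(-1, 2)
    d = coords[edges[:, 1]] - coords[edges[:, 0]]
    dist = np.linalg.norm(d, axis=1, keepdims=True)
    return np.hstack([dist, d]) / feature_scale


def suggest_delta(coords: np.ndarray, q: float = 95.0) -> float:
    """Data-driven edge-length threshold.

    Returns the q-th percentile of unfiltered Delaunay edge lengths — a
    reproducible stand-in for a density-matched manual choice.
    """
    coords = np.asarray(coords, float)
    edges = delaunay_filtered_edges(coords, np.inf)
    if len(edges) == 0:
        raise ValueError("not enough points to suggest delta")
    lengths = np.linalg.norm(coords[edges[:, 0]] - coords[edges[:, 1]], axis=1)
    return float(np.percentile(lengths, q))


def save_graph(path, graph: PointGraph) -> None:
    """Cache a built graph to a compressed archive."""
    np.savez_compressed(path, coords=graph.coords, edges=graph.edges,
                        node_features=graph.node_features,
                        edge_features=graph.edge_features,
                        feature_scale=np.array(graph.feature_scale))


def load_graph(path) -> PointGraph:
    """Load a graph cached by :func:`save_graph`."""
    with np.load(path) as npz:
        return PointGraph(coords=npz["coords"], edges=npz["edges"],
                          node_features=npz["node_features"],
                          edge_features=npz["edge_features"],
                          feature_scale=float(npz["feature_scale"]))


def build_graph(table, cfg: GraphConfig) -> PointGraph:
    """Build the network input graph from a localization table.

    ``table`` may be a DataFrame with x/y columns or an (N, 2) array.
    """
    if hasattr(table, "columns"):
        coords = table[["x", "y"]].to_numpy(float)
    else:
        coords = np.asarray(table, float).reshape(-1, 2)
    edges = delaunay_filtered_edges(coords, cfg.delta)
    node_features = laplacian_embeddings(edges, len(coords), cfg.n_eig)
    edge_features = edge_feature_vectors(coords, edges, cfg.scale)
    return PointGraph(coords=coords, edges=edges, node_features=node_features,
                      edge_features=edge_features, feature_scale=cfg.scale)
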