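"""Cluster-evaluation metrics.

Partition indices: the adjusted Rand index (ARI, pair-counting with the
permutation-model correction, background treated as an ordinary
cluster), a robust variant (ARI-dagger) built from *unweighted* averages
of per-cluster adjusted Wallace indices, adjusted mutual information
(AMI, arithmetic-mean normalizer) and the ARI restricted to truly
clustered localizations (ARI_c).

Cluster-level detection metrics: ground-truth and predicted clusters
are paired by a Hungarian assignment — on centroid distances with a
rejection threshold xi, or on shared-localization overlap — giving
TP/FP/FN counts, from which the detection Jaccard index
JI_c = TP / (TP + FP + FN), the RMS relative error of cluster sizes
RMSRE_N and the RMS centroid error RMSE_xy follow. Convex-hull IoU
compares the union of per-cluster hulls. The compression index
quantifies how completely a displacement field contracts clusters
toward their centroids, and the Dirichlet energy of node features
diagnoses oversmoothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import comb
from shapely.geometry import MultiPoint
from shapely.ops import unary_union
from sklearn.metrics import adjusted_mutual_info_score

__all__ = [
    "Contingency",
    "MatchResult",
    "contingency",
    "labels_from_contingency",
    "ari",
    "ari_dagger",
    "ami",
    "ari_c",
    "cluster_sizes",
    "cluster_centroids",
    "default_xi",
    "match_clusters",
    "ji_c",
    "rmsre_n",
    "rmse_xy",
    "iou_hulls",
    "compression_index",
    "dirichlet_energy",
    "example_imbalanced_partitions",
    "evaluate",
]


@dataclass
class Contingency:
    """Cross-tabulation of two labelings (background is an ordinary label)."""

    counts: np.ndarray          # (n_true_labels, n_pred_labels) int
    true_ids: np.ndarray
    pred_ids: np.ndarray

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def contingency(true_labels, pred_labels) -> Contingency:
    t = np.asarray(true_labels, int)
    p = np.asarray(pred_labels, int)
    if t.shape != p.shape:
        raise ValueError("label vectors differ in length")
    tids, ti = np.unique(t, return_inverse=True)
    pids, pi = np.unique(p, return_inverse=True)
    C = np.zeros((len(tids), len(pids)), dtype=int)
    np.add.at(C, (ti, pi), 1)
    return Contingency(C, tids, pids)


def labels_from_contingency(cont: Contingency):
    """Expand a contingency table back into aligned label vectors."""
    t, p = [], []
    C = cont.counts
    for i in range(C.shape[0]):
        for j in range(C.shape[1]):
            t.extend([cont.true_ids[i]] * C[i, j])
            p.extend([cont.pred_ids[j]] * C[i, j])
    return np.array(t, int), np.array(p, int)


def _as_contingency(x, y=None) -> Contingency:
    if isinstance(x, Contingency):
        return x
    if y is None:
        return Contingency(np.asarray(x, int), np.arange(np.shape(x)[0]),
                           np.arange(np.shape(x)[1]))
    return contingency(x, y)


def ari(x, y=None) -> float:
    """Adjusted Rand index (pair counting, permutation-model expectation).

    Accepts either two label vectors or a contingency table/array.
    Degenerate cases where the expectation equals the maximum (e.g. both
    partitions trivial) return 1.0 for identical partitions.
    """
    cont = _as_contingency(x, y)
    C = cont.counts
    n = cont.n
    if n < 2:
        raise ValueError("ARI needs at least 2 points")
    a = C.sum(axis=1)
    b = C.sum(axis=0)
    index = comb(C, 2).sum()
    sum_a = comb(a, 2).sum()
    sum_b = comb(b, 2).sum()
    expected = sum_a * sum_b / comb(n, 2)
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((index - expected) / (max_index - expected))


def _adjusted_wallace_per_cluster(C: np.ndarray) -> np.ndarray:
    """Adjusted Wallace-type index of each row cluster against the columns."""
    n = C.sum()
    a = C.sum(axis=1)
    b = C.sum(axis=0)
    e = comb(b, 2).sum() / comb(n, 2)   # chance pair-agreement rate
    rows = np.flatnonzero(a >= 2)
    w = np.array([comb(C[i], 2).sum() / comb(a[i], 2) for i in rows])
    if e >= 1.0:   # opposite partition is a single cluster: no chance correction
        return np.full(len(rows), np.nan)
    return (w - e) / (1.0 - e)


def ari_dagger(x, y=None) -> float:
    """Imbalance-robust ARI variant.

    The classical ARI is the harmonic mean of the two adjusted Wallace
    indices, each a *size-weighted* (quadratically) mean of per-cluster
    indices, which lets large clusters dominate. This variant averages
    the per-cluster adjusted indices with ordinary (unweighted) means in
    both directions and takes the harmonic mean of the two results.
    """
    cont = _as_contingency(x, y)
    C = cont.counts.astype(float)
    if C.shape[0] == 1 and C.shape[1] == 1:
        return 1.0
    aw_rows = _adjusted_wallace_per_cluster(C)
    aw_cols = _adjusted_wallace_per_cluster(C.T)
    if len(aw_rows) == 0 or len(aw_cols) == 0:
        return float("nan")
    m1, m2 = aw_rows.mean(), aw_cols.mean()
    if m1 + m2 == 0:
        return 0.0
    return float(2.0 * m1 * m2 / (m1 + m2))


def ami(x, y=None) -> float:
    """Adjusted mutual information (hypergeometric expectation,
    arithmetic-mean entropy normalizer)."""
    cont = _as_contingency(x, y)
    t, p = labels_from_contingency(cont)
    if len(t) < 2:
        raise ValueError("AMI needs at least 2 points")
    return float(adjusted_mutual_info_score(t, p, average_method="arithmetic"))


def ari_c(true_labels, pred_labels, background: int = -1) -> float:
    """ARI excluding truly non-clustered localizations.

    Rows whose *true* label equals ``background`` are dropped; predicted
    labels are kept as-is (a predicted background group simply becomes
    an ordinary cluster among the retained rows).
    """
    t = np.asarray(true_labels, int)
    p = np.asarray(pred_labels, int)
    m = t != background
    if not m.any():
        raise ValueError("no clustered rows; ARI_c undefined")
    return ari(t[m], p[m])


# ---------------------------------------------------------------------------
# Cluster matching and detection metrics
# ---------------------------------------------------------------------------

def cluster_sizes(labels, background: int = -1) -> dict[int, int]:
    labels = np.asarray(labels, int)
    ids, counts = np.unique(labels[labels != background], return_counts=True)
    return dict(zip(ids.tolist(), counts.tolist()))


def cluster_centroids(labels, coords, background: int = -1) -> dict[int, np.ndarray]:
    labels = np.asarray(labels, int)
    coords = np.asarray(coords, float)
    return {int(lab): coords[labels == lab].mean(axis=0)
            for lab in np.unique(labels) if lab != background}


def default_xi(labels, coords, background: int = -1) -> float:
    """Default matching threshold: twice the mean RMS cluster radius."""
    labels = np.asarray(labels, int)
    coords = np.asarray(coords, float)
    radii = []
    for lab in np.unique(labels):
        if lab == background:
            continue
        pts = coords[labels == lab]
        radii.append(np.sqrt(((pts - pts.mean(0)) ** 2).sum(1).mean()))
    if not radii:
        raise ValueError("no clusters to derive xi from")
    return 2.0 * float(np.mean(radii))


@dataclass
class MatchResult:
    """Hungarian pairing between ground-truth and predicted clusters."""

    pairs: list = field(default_factory=list)   # [(true_id, pred_id), ...]
    tp: int = 0
    fp: int = 0
    fn: int = 0
    xi: float | None = None

    @property
    def true_matched(self):
        return [t for t, _ in self.pairs]

    @property
    def pred_matched(self):
        return [p for _, p in self.pairs]


def match_clusters(true_labels, pred_labels, coords=None, mode: str = "centroid",
                   xi: float | None = None, background: int = -1) -> MatchResult:
    """Pair clusters of two labelings with a Hungarian assignment.

    ``centroid`` mode minimizes total centroid distance and rejects
    pairs farther apart than ``xi`` (default: twice the mean RMS radius
    of the true clusters). ``overlap`` mode maximizes total shared
    localizations and rejects empty overlaps; it needs no coordinates.
    Unmatched predicted clusters count as FP, unmatched true clusters
    as FN. Ties are broken toward lexicographically smallest pairs.
    """
    t = np.asarray(true_labels, int)
    p = np.asarray(pred_labels, int)
    true_ids = [int(l) for l in np.unique(t) if l != background]
    pred_ids = [int(l) for l in np.unique(p) if l != background]
    if not true_ids or not pred_ids:
        return MatchResult(tp=0, fp=len(pred_ids), fn=len(true_ids), xi=xi)

    if mode == "centroid":
        if coords is None:
            raise ValueError("centroid mode requires coordinates")
        coords = np.asarray(coords, float)
        if xi is None:
            xi = default_xi(t, coords, background)
        tc = np.array([coords[t == l].mean(0) for l in true_ids])
        pc = np.array([coords[p == l].mean(0) for l in pred_ids])
        D = np.linalg.norm(tc[:, None, :] - pc[None, :, :], axis=2)
        big = max(1.0, 10.0 * xi) * (len(true_ids) + len(pred_ids) + 1)
        cost = np.where(D <= xi, D, big)
        accept = lambda i, j: D[i, j] <= xi
    elif mode == "overlap":
        cont = np.zeros((len(true_ids), len(pred_ids)))
        tmap = {l: i for i, l in enumerate(true_ids)}
        pmap = {l: j for j, l in enumerate(pred_ids)}
        m = (t != background) & (p != background)
        np.add.at(cont, ([tmap[int(a)] for a in t[m]], [pmap[int(b)] for b in p[m]]), 1)
        cost = -cont
        accept = lambda i, j: cont[i, j] > 0
    else:
        raise ValueError("mode must be 'centroid' or 'overlap'")

    # deterministic tie-break: nudge costs toward small (i, j) pairs
    eps = np.abs(cost).max() or 1.0
    tie = (np.arange(len(true_ids))[:, None] * len(pred_ids)
           + np.arange(len(pred_ids))[None, :])
    rows, cols = linear_sum_assignment(cost + 1e-9 * eps * tie
                                       / max(tie.size, 1))
    pairs = [(true_ids[i], pred_ids[j]) for i, j in zip(rows, cols) if accept(i, j)]
    tp = len(pairs)
    return MatchResult(pairs=pairs, tp=tp, fp=len(pred_ids) - tp,
                       fn=len(true_ids) - tp, xi=xi)


def ji_c(match: MatchResult) -> float:
    """Detection Jaccard index TP / (TP + FP + FN)."""
    denom = match.tp + match.fp + match.fn
    if denom == 0:
        return float("nan")
    return match.tp / denom


def rmsre_n(match: MatchResult, true_sizes: dict, pred_sizes: dict) -> float:
    """RMS relative error of matched cluster sizes.

    The predicted size is the *total* membership of the matched
    predicted cluster, contaminating/background rows included.
    """
    if match.tp == 0:
        raise ValueError("RMSRE_N needs at least one matched pair")
    rel = [(pred_sizes[pl] - true_sizes[tl]) / true_sizes[tl]
           for tl, pl in match.pairs]
    return float(np.sqrt(np.mean(np.square(rel))))


def rmse_xy(match: MatchResult, true_centroids: dict, pred_centroids: dict) -> float:
    """RMS error of matched cluster centroid positions (nm)."""
    if match.tp == 0:
        raise ValueError("RMSE_xy needs at least one matched pair")
    sq = [((pred_centroids[pl] - true_centroids[tl]) ** 2).sum()
          for tl, pl in match.pairs]
    return float(np.sqrt(np.mean(sq)))


def iou_hulls(true_labels, pred_labels, coords, background: int = -1) -> float:
    """Intersection-over-union of the unions of per-cluster convex hulls.

    Clusters with fewer than 3 non-collinear points contribute no hull.
    Returns NaN when both unions are empty.
    """
    coords = np.asarray(coords, float)

    def hull_union(labels):
        hulls = []
        labels = np.asarray(labels, int)
        for lab in np.unique(labels):
            if lab == background:
                continue
            pts = coords[labels == lab]
            if len(pts) < 3:
                continue
            h = MultiPoint(pts).convex_hull
            if h.area > 0:
                hulls.append(h)
        return unary_union(hulls) if hulls else None

    ut = hull_union(true_labels)
    up = hull_union(pred_labels)
    if ut is None and up is None:
        return float("nan")
    if ut is None or up is None:
        return 0.0
    inter = ut.intersection(up).area
    union = ut.union(up).area
    return float(inter / union) if union > 0 else float("nan")


# ---------------------------------------------------------------------------
# Displacement-field diagnostics
# ---------------------------------------------------------------------------

def compression_index(coords, displacements, labels, background: int = -1) -> float:
    """How completely displacements contract clusters toward centroids.

    Per cluster: 1 minus the ratio of summed distances to the centroid
    after and before displacement, averaged over clusters. 1 means all
    points land exactly on their cluster centroid; 0 means no
    contraction. Clusters whose members all coincide with the centroid
    are skipped with a warning.
    """
    coords = np.asarray(coords, float)
    displacements = np.asarray(displacements, float)
    labels = np.asarray(labels, int)
    vals = []
    for lab in np.unique(labels):
        if lab == background:
            continue
        m = labels == lab
        mu = coords[m].mean(axis=0)
        before = np.linalg.norm(coords[m] - mu, axis=1).sum()
        if before == 0:
            warnings.warn(f"cluster {lab} has zero radius; skipped")
            continue
        after = np.linalg.norm(coords[m] + displacements[m] - mu, axis=1).sum()
        vals.append(1.0 - after / before)
    if not vals:
        return float("nan")
    return float(np.mean(vals))


def dirichlet_energy(node_features, edges) -> float:
    """Mean (over nodes) summed squared feature difference across edges.

    ``edges`` must contain both orientations of every undirected edge;
    a value near zero on heterogeneous input diagnoses oversmoothing.
    """
    u = np.asarray(node_features, float)
    if u.ndim == 1:
        u = u[:, None]
    edges = np.asarray(edges, int).reshape(-1, 2)
    n = len(u)
    if n == 0:
        return 0.0
    diff = u[edges[:, 0]] - u[edges[:, 1]]
    return float((diff ** 2).sum() / n)


def example_imbalanced_partitions() -> dict[str, Contingency]:
    """Two worked-example clusterings of a heavily imbalanced FOV.

    The ground truth has 20 clusters of 50 localizations plus 1000
    background localizations (a typical SMLM imbalance). Method ``A``
    finds all 20 clusters but absorbs 10 background points into each
    while sending 5 true members of each cluster to the background.
    Method ``B`` recognizes background better (10% error) but splits
    half of the clusters in two (members 21 + 20 after losing 9 to
    background; the larger halves and the intact clusters each absorb
    5 background points). Together they illustrate why the ARI alone
    misranks methods under imbalance while ARI-dagger, AMI, ARI_c and
    the detection metrics do not. Background uses label -1.
    """
    # method A: true background row then 20 true clusters
    A = np.zeros((21, 21), dtype=int)
    A[0, 0] = 800
    A[0, 1:] = 10
    for i in range(1, 21):
        A[i, 0] = 5
        A[i, i] = 45
    # method B: 30 predicted clusters
    B = np.zeros((21, 31), dtype=int)
    B[0, 0] = 900
    contaminated = list(range(1, 11)) + list(range(11, 31, 2))
    for j in contaminated:
        B[0, j] = 5
    for i in range(1, 11):
        B[i, 0] = 9
        B[i, i] = 41
    for k, i in enumerate(range(11, 21)):
        B[i, 0] = 9
        B[i, 11 + 2 * k] = 21
        B[i, 12 + 2 * k] = 20
    ids21 = np.arange(21) - 1   # -1 = background, then clusters 0..19
    ids31 = np.arange(31) - 1
    return {
        "A": Contingency(A, ids21.copy(), ids21.copy()),
        "B": Contingency(B, ids21.copy(), ids31),
    }


# ---------------------------------------------------------------------------
# Full panel
# ---------------------------------------------------------------------------

def evaluate(true_labels, pred_labels, coords=None, xi: float | None = None,
             match_mode: str = "centroid", background: int = -1) -> dict:
    """Compute the full metric panel for one field of view.

    Returns a dict with keys ``ari, ari_dagger, ami, ari_c, ji_c,
    rmsre_n, rmse_xy, iou`` (the last three NaN when no coordinates are
    given or no pair matched).
    """
    t = np.asarray(true_labels, int)
    p = np.asarray(pred_labels, int)
    rep = {
        "ari": ari(t, p),
        "ari_dagger": ari_dagger(t, p),
        "ami": ami(t, p),
        "ari_c": ari_c(t, p, background) if (t != background).any() else float("nan"),
    }
    mode = match_mode if coords is not None else "overlap"
    match = match_clusters(t, p, coords, mode=mode, xi=xi, background=background)
    rep["ji_c"] = ji_c(match)
    if match.tp > 0:
        rep["rmsre_n"] = rmsre_n(match, cluster_sizes(t, background),
                                 cluster_sizes(p, background))
        if coords is not None:
            rep["rmse_xy"] = rmse_xy(match, cluster_centroids(t, coords, background),
                                     cluster_centroids(p, coords, background))
        else:
            rep["rmse_xy"] = float("nan")
    else:
        rep["rmsre_n"] = float("nan")
        rep["rmse_xy"] = float("nan")
    rep["iou"] = iou_hulls(t, p, coords, background) if coords is not None else float("nan")
    return rep
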