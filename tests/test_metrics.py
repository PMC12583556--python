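"""Metric panel: formula conformance, oracles, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from miro.metrics import (ami, ari, ari_c, ari_dagger, cluster_centroids,
                          cluster_sizes, compression_index, contingency,
                          dirichlet_energy, evaluate,
                          example_imbalanced_partitions, iou_hulls, ji_c,
                          labels_from_contingency, match_clusters, rmse_xy,
                          rmsre_n)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def ari_pair_counting(t, p):
    """O(n^2) adjusted Rand index: enumerate all point pairs."""
    t, p = np.asarray(t), np.asarray(p)
    n = len(t)
    a = b = c = d = 0
    for i in range(n):
        for j in range(i + 1, n):
            st_, sp = t[i] == t[j], p[i] == p[j]
            if st_ and sp:
                a += 1
            elif st_:
                c += 1
            elif sp:
                d += 1
            else:
                b += 1
    total = a + b + c + d
    exp = (a + c) * (a + d) / total
    mx = ((a + c) + (a + d)) / 2.0
    if mx == exp:
        return 1.0
    return (a - exp) / (mx - exp)


def rasterized_iou(true_labels, pred_labels, coords, step=0.5):
    """Grid-rasterization oracle for convex-hull IoU."""
    from shapely.geometry import MultiPoint
    from shapely.ops import unary_union

    def union_of(labels):
        hulls = [MultiPoint(coords[labels == l]).convex_hull
                 for l in np.unique(labels) if l >= 0
                 if (labels == l).sum() >= 3]
        hulls = [h for h in hulls if h.area > 0]
        return unary_union(hulls) if hulls else None

    ut, up = union_of(np.asarray(true_labels)), union_of(np.asarray(pred_labels))
    lo = coords.min(0) - 1
    hi = coords.max(0) + 1
    xs = np.arange(lo[0], hi[0], step)
    ys = np.arange(lo[1], hi[1], step)
    gx, gy = np.meshgrid(xs, ys)
    from shapely import points, contains
    pts = points(np.column_stack([gx.ravel(), gy.ravel()]))
    int_ = contains(ut, pts)
    inp = contains(up, pts)
    inter = (int_ & inp).sum()
    union = (int_ | inp).sum()
    return inter / union


# ---------------------------------------------------------------------------
# worked-example conformance (methods A and B)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def toy():
    return example_imbalanced_partitions()


@pytest.mark.parametrize("method,expected", [
    ("A", {"ari": 0.62, "ari_dagger": 0.67, "ami": 0.70, "ari_c": 0.80}),
    ("B", {"ari": 0.65, "ari_dagger": 0.47, "ami": 0.67, "ari_c": 0.46}),
])
def test_partition_indices_on_imbalanced_example(toy, method, expected):
    """The four partition indices reproduce the worked example to 2 decimals."""
    cont = toy[method]
    t, p = labels_from_contingency(cont)
    assert ari(cont) == pytest.approx(expected["ari"], abs=0.005)
    assert ari_dagger(cont) == pytest.approx(expected["ari_dagger"], abs=0.005)
    assert ami(cont) == pytest.approx(expected["ami"], abs=0.005)
    assert ari_c(t, p) == pytest.approx(expected["ari_c"], abs=0.005)


@pytest.mark.parametrize("method,tp,fp,fn,jic,rmsre", [
    ("A", 20, 0, 0, 1.0, 0.1),
    ("B", 20, 10, 0, 2 / 3, 0.34),
])
def test_detection_metrics_on_imbalanced_example(toy, method, tp, fp, fn, jic, rmsre):
    """Overlap matching, JI_c and RMSRE_N reproduce the worked example."""
    t, p = labels_from_contingency(toy[method])
    m = match_clusters(t, p, mode="overlap")
    assert (m.tp, m.fp, m.fn) == (tp, fp, fn)
    assert ji_c(m) == pytest.approx(jic, abs=0.005)
    assert rmsre_n(m, cluster_sizes(t), cluster_sizes(p)) == pytest.approx(rmsre, abs=0.005)


# ---------------------------------------------------------------------------
# ARI family
# ---------------------------------------------------------------------------

def test_identical_partitions_score_one():
    labels = np.array([0, 0, 1, 1, 2, 2, -1, -1])
    assert ari(labels, labels) == pytest.approx(1.0)
    assert ari_dagger(labels, labels) == pytest.approx(1.0)
    assert ami(labels, labels) == pytest.approx(1.0)
    assert ari_c(labels, labels) == pytest.approx(1.0)


def test_ari_matches_pair_counting_oracle():
    rng = np.random.default_rng(7)
    for _ in range(5):
        n = int(rng.integers(10, 200))
        t = rng.integers(0, 5, n)
        p = rng.integers(0, 6, n)
        assert ari(t, p) == pytest.approx(ari_pair_counting(t, p), abs=1e-10)


@given(st.lists(st.tuples(st.integers(0, 3), st.integers(0, 3)),
                min_size=5, max_size=40))
@settings(deadline=None, max_examples=30)
def test_partition_indices_invariant_to_relabeling(pairs):
    """Renaming cluster ids on either side never changes a partition index."""
    t = np.array([a for a, _ in pairs])
    p = np.array([b for _, b in pairs])
    perm = {0: 7, 1: 3, 2: 9, 3: 0}
    t2 = np.array([perm[int(a)] for a in t])
    p2 = np.array([perm[int(b)] for b in p])
    assert ari(t, p) == pytest.approx(ari(t2, p2), abs=1e-12)
    assert ami(t, p) == pytest.approx(ami(t2, p2), abs=1e-9)
    d1, d2 = ari_dagger(t, p), ari_dagger(t2, p2)
    if np.isnan(d1):
        assert np.isnan(d2)
    else:
        assert d1 == pytest.approx(d2, abs=1e-12)


def test_ari_c_ignores_background_errors():
    """Perfect prediction on clustered rows scores 1 regardless of background."""
    t = np.array([-1] * 10 + [0] * 5 + [1] * 5)
    p = np.concatenate([np.arange(10), np.full(5, 50), np.full(5, 60)])
    assert ari_c(t, p) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        ari_c(np.full(5, -1), np.zeros(5))


# ---------------------------------------------------------------------------
# matching and cluster-level metrics
# ---------------------------------------------------------------------------

def test_centroid_matching_threshold_rejection():
    coords = np.array([[0.0, 0.0], [0.0, 0.1], [10.0, 0.0], [10.0, 0.1]])
    t = np.array([0, 0, -1, -1])
    p = np.array([-1, -1, 0, 0])
    m = match_clusters(t, p, coords, mode="centroid", xi=5.0)
    assert (m.tp, m.fp, m.fn) == (0, 1, 1)
    assert ji_c(m) == 0.0
    m2 = match_clusters(t, p, coords, mode="centroid", xi=20.0)
    assert (m2.tp, m2.fp, m2.fn) == (1, 0, 0)


def test_identical_clusterings_match_perfectly():
    rng = np.random.default_rng(3)
    coords = rng.uniform(0, 100, (40, 2))
    labels = np.repeat(np.arange(4), 10)
    m = match_clusters(labels, labels, coords, mode="centroid")
    assert (m.tp, m.fp, m.fn) == (4, 0, 0)
    cents = cluster_centroids(labels, coords)
    assert rmse_xy(m, cents, cents) == 0.0


def test_adding_spurious_cluster_strictly_lowers_jic():
    t = np.repeat(np.arange(3), 5)
    p = t.copy()
    coords = np.repeat(np.array([[0.0, 0], [100, 0], [0, 100]]), 5, axis=0)
    base = ji_c(match_clusters(t, p, coords, xi=10.0))
    p2 = p.copy()
    p2[0] = 99   # split off a spurious singleton cluster far from others
    worse = ji_c(match_clusters(t, p2, coords, xi=10.0))
    assert worse < base


def test_rmse_xy_constant_offset():
    t = np.repeat(np.arange(2), 4)
    cents_t = {0: np.array([0.0, 0.0]), 1: np.array([50.0, 0.0])}
    cents_p = {0: np.array([3.0, 4.0]), 1: np.array([53.0, 4.0])}
    m = match_clusters(t, t, mode="overlap")
    assert rmse_xy(m, cents_t, cents_p) == pytest.approx(5.0)


# ---------------------------------------------------------------------------
# hull IoU
# ---------------------------------------------------------------------------

def test_iou_identical_and_disjoint():
    rng = np.random.default_rng(1)
    coords = np.vstack([rng.uniform(0, 10, (10, 2)), rng.uniform(100, 110, (10, 2))])
    labels = np.repeat([0, 1], 10)
    assert iou_hulls(labels, labels, coords) == pytest.approx(1.0)
    only_a = np.where(labels == 0, 0, -1)
    only_b = np.where(labels == 1, 0, -1)
    assert iou_hulls(only_a, only_b, coords) == 0.0


def test_iou_matches_rasterization_oracle():
    rng = np.random.default_rng(5)
    coords = rng.uniform(0, 60, (60, 2))
    t = rng.integers(0, 3, 60)
    p = rng.integers(0, 3, 60)
    assert iou_hulls(t, p, coords) == pytest.approx(
        rasterized_iou(t, p, coords), abs=0.01)


# ---------------------------------------------------------------------------
# displacement diagnostics
# ---------------------------------------------------------------------------

def test_compression_index_hand_cases():
    rng = np.random.default_rng(2)
    coords = rng.normal(0, 20, (30, 2)) + 100
    labels = np.repeat(np.arange(3), 10)
    cent = np.vstack([coords[labels == l].mean(0) for l in range(3)])[labels]
    full = cent - coords
    assert compression_index(coords, np.zeros_like(coords), labels) == pytest.approx(0.0)
    assert compression_index(coords, full, labels) == pytest.approx(1.0)
    assert compression_index(coords, full / 2, labels) == pytest.approx(0.5)


def test_dirichlet_energy_hand_case_and_homogeneity():
    feats = np.array([[0.0], [1.0]])
    edges = np.array([[0, 1], [1, 0]])
    assert dirichlet_energy(feats, edges) == pytest.approx(1.0)
    assert dirichlet_energy(3.0 * feats, edges) == pytest.approx(9.0)
    assert dirichlet_energy(np.ones((5, 4)), np.array([[0, 1], [1, 0], [2, 3], [3, 2]])) == 0.0


def test_evaluate_self_comparison_is_perfect():
    rng = np.random.default_rng(11)
    coords = np.vstack([rng.normal(c, 2, (8, 2)) for c in ((0, 0), (50, 0), (0, 50))])
    labels = np.repeat(np.arange(3), 8)
    rep = evaluate(labels, labels, coords)
    assert rep["ari"] == pytest.approx(1.0)
    assert rep["ami"] == pytest.approx(1.0)
    assert rep["ji_c"] == pytest.approx(1.0)
    assert rep["rmsre_n"] == 0.0
    assert rep["rmse_xy"] == 0.0
    assert rep["iou"] == pytest.approx(1.0)
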