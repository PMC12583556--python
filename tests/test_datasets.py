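"""Synthetic-data generators: counts, geometry, determinism, blinking."""

import math

import numpy as np
import pandas as pd
import pytest

from miro._rng import substream
from miro.datasets import (AugmentConfig, SimScenario, apply_blinking,
                           extract_clusters, make_training_set,
                           sample_npc_corner, simulate_arc_clusters,
                           simulate_cluster_pair, simulate_npc,
                           simulate_rings_of_spots, simulate_scenario)


# ---------------------------------------------------------------------------
# benchmark scenarios
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("sid,n_clustered,n_total", [
    ("S2", 300, 600),
    ("S3", 300, 1500),
    ("S4", 100, 400),
    ("S5", 1500, 3000),
    ("S6", 1000, 2000),
    ("S8", 200, 400),
    ("S10", 300, 600),
])
def test_scenario_count_conservation(sid, n_clustered, n_total):
    t = simulate_scenario(SimScenario(sid, seed=5))
    assert len(t) == n_total
    assert (t["label"] >= 0).sum() == n_clustered
    assert (t["label"] == -1).sum() == n_total - n_clustered


def test_scenario_s6_is_elliptical_3_to_1():
    t = simulate_scenario(SimScenario("S6", seed=1))
    assert t["label"].max() + 1 == 20
    ratios = []
    for lab, grp in t[t.label >= 0].groupby("label"):
        pts = grp[["x", "y"]].to_numpy()
        w = np.linalg.eigvalsh(np.cov(pts.T))
        ratios.append(math.sqrt(w[1] / w[0]))
    # per-cluster sample aspect ratio concentrates near 3
    assert 2.2 < np.median(ratios) < 4.0


def test_scenario_s8_group_structure():
    t = simulate_scenario(SimScenario("S8", seed=2))
    sizes = sorted(t[t.label >= 0].groupby("label").size())
    assert sizes == [5] * 10 + [15] * 10


def test_seeded_determinism_across_generators():
    for make in (lambda s: simulate_scenario(SimScenario("S8", seed=s)),
                 lambda s: simulate_arc_clusters("ring", seed=s),
                 lambda s: simulate_npc(seed=s),
                 lambda s: simulate_rings_of_spots(seed=s),
                 lambda s: simulate_cluster_pair(2.0, seed=s)):
        a, b = make(7), make(7)
        pd.testing.assert_frame_equal(a, b)
        assert not a.equals(make(8))


def test_unknown_scenario_rejected():
    with pytest.raises(ValueError):
        SimScenario("S99")


def test_background_inside_fov_and_gradient_background():
    t = simulate_scenario(SimScenario("S10", seed=3))
    bg = t[t.label == -1]
    assert bg["x"].between(0, 2000).all() and bg["y"].between(0, 2000).all()
    # left-to-right density ramp: right half holds ~3/4 of background
    frac_right = (bg["x"] > 1000).mean()
    assert 0.65 < frac_right < 0.85


# ---------------------------------------------------------------------------
# blinking
# ---------------------------------------------------------------------------

def test_blinking_expansion_mean_and_inheritance():
    rng = np.random.default_rng(0)
    table = pd.DataFrame({"x": rng.uniform(0, 100, 10_000),
                          "y": rng.uniform(0, 100, 10_000),
                          "label": rng.integers(-1, 5, 10_000)})
    out = apply_blinking(table, mean_locs=4.5, precision=5.0, seed=1)
    # law of large numbers: expansion factor within 3 standard errors
    n = len(table)
    se = math.sqrt(3.5 / n)   # var of 1+Poisson(3.5) per molecule
    assert abs(len(out) / n - 4.5) < 3 * se * 4.5
    # label multiset: every child label existed among parents
    assert set(out["label"]) == set(table["label"])


def test_blinking_zero_precision_children_coincide():
    table = pd.DataFrame({"x": [1.0, 2.0], "y": [3.0, 4.0], "label": [0, 1]})
    out = apply_blinking(table, mean_locs=3.0, precision=0.0, seed=0)
    assert set(map(tuple, out[["x", "y"]].to_numpy())) == {(1.0, 3.0), (2.0, 4.0)}
    empty = apply_blinking(table.iloc[:0], 4.5, 5.0, seed=0)
    assert len(empty) == 0


# ---------------------------------------------------------------------------
# arc-shaped clusters
# ---------------------------------------------------------------------------

def test_c_shape_defaults_and_geometry():
    t = simulate_arc_clusters("c_shape", seed=11)
    n_clusters = t["label"].max() + 1
    assert 30 <= n_clusters <= 60
    sizes = t[t.label >= 0].groupby("label").size()
    assert sizes.between(30, 60).all()
    # background share of total ~6%
    assert abs((t.label == -1).mean() - 0.06) < 0.005
    # radial distances concentrate around 250 +- 50
    grp = t[t.label == 0][["x", "y"]].to_numpy()
    r = np.linalg.norm(grp - grp.mean(0), axis=1)
    assert 150 < r.mean() < 320


def test_ring_defaults_and_no_background_option():
    t = simulate_arc_clusters("ring", seed=4)
    n_clusters = t["label"].max() + 1
    assert 60 <= n_clusters <= 70
    assert t[t.label >= 0].groupby("label").size().between(60, 80).all()
    assert abs((t.label == -1).mean() - 0.07) < 0.005
    t0 = simulate_arc_clusters("ring", seed=4, background_fraction=0.0)
    assert (t0["label"] >= 0).all()
    with pytest.raises(ValueError):
        simulate_arc_clusters("ring", radial_sd=-1.0)


def test_arc_minimum_center_separation():
    t = simulate_arc_clusters("ring", seed=13)
    cents = np.array([g[["x", "y"]].mean().to_numpy()
                      for _, g in t[t.label >= 0].groupby("label")])
    d = np.linalg.norm(cents[:, None] - cents[None, :], axis=2)
    np.fill_diagonal(d, np.inf)
    # ring centroids sit near the placement centers; separation ~ 2*radius
    assert np.median(d.min(axis=1)) > 400.0


# ---------------------------------------------------------------------------
# NPC-like structures and rings of spots
# ---------------------------------------------------------------------------

def test_npc_has_eight_corner_slots_and_count_bounds():
    t = simulate_npc(seed=3)
    clustered = t[t.label >= 0]
    for lab, grp in clustered.groupby("label"):
        assert grp["sublabel"].nunique() <= 8
    per_corner = clustered.groupby("sublabel").size()
    assert per_corner.between(0, 80).all()
    # corner slots are globally unique ids: 8 per structure
    n_structures = t["label"].max() + 1
    assert 5 <= n_structures <= 9


def test_npc_corner_radial_envelope():
    """Monte-Carlo check of the corner geometry.

    Radial distances from the structure center concentrate at the ring
    radius (50 nm), and the one-sigma reach along the corner bisector
    spans roughly 20 nm (inward) to 80 nm (outward) — the corner's
    effective inner and outer radii.
    """
    rng = substream(0, "npc-mc")
    pts = sample_npc_corner(100_000, rng)
    r = np.linalg.norm(pts, axis=1)   # distance from the structure center
    assert abs(np.median(r) - 50.0) < 8.0
    # points emitted within ~20 deg of the bisector, inward / outward
    ang = np.arctan2(pts[:, 1], pts[:, 0] - 50.0)
    inward = r[np.abs(np.abs(ang) - np.pi) < 0.35]
    outward = r[np.abs(ang) < 0.35]
    assert 15.0 < np.percentile(inward, 16) < 30.0    # ~ -1 sigma reach
    assert 70.0 < np.percentile(outward, 84) < 90.0   # ~ +1 sigma reach


def test_rings_of_spots_symmetry_and_radius():
    t = simulate_rings_of_spots(seed=6)
    clustered = t[t.label >= 0]
    dists = []
    for lab, grp in clustered.groupby("label"):
        fold = grp["sublabel"].nunique()
        assert 5 <= fold <= 9
        center = grp[["x", "y"]].mean().to_numpy()
        for _, spot in grp.groupby("sublabel"):
            dists.append(np.linalg.norm(spot[["x", "y"]].mean().to_numpy() - center))
    # mean spot-to-ring-center distance ~ 40 nm
    assert abs(np.mean(dists) - 40.0) < 6.0


def test_cluster_pair_geometry_and_counts():
    t = simulate_cluster_pair(0.0, seed=1)
    c0 = t[t.label == 0][["x", "y"]].mean()
    c1 = t[t.label == 1][["x", "y"]].mean()
    assert np.linalg.norm(c0 - c1) < 15.0   # coincident centers up to noise
    # sd ~ 25 nm and geometric counts with mean 90 (Monte Carlo)
    sds, counts = [], []
    for s in range(300):
        tt = simulate_cluster_pair(4.0, seed=s)
        for lab in (0, 1):
            pts = tt[tt.label == lab][["x", "y"]].to_numpy()
            counts.append(len(pts))
            if len(pts) > 10:
                sds.append(pts.std(0, ddof=1).mean())
    assert abs(np.mean(sds) - 25.0) < 2.0
    assert abs(np.mean(counts) - 90.0) < 3 * 90 / math.sqrt(len(counts))


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def test_identity_augmentation_reproduces_source_up_to_translation():
    rng = np.random.default_rng(2)
    src = rng.normal(0, 10, (20, 2))
    cfg = AugmentConfig(n_pointclouds=3, rotation=False, reflection=False,
                        dropout_fraction=0.0, addition_fraction=0.0,
                        jitter_sd=0.0, background_fraction=0.0,
                        clusters_per_fov=(1, 1), fov_size=500.0, seed=0)
    fovs = make_training_set([src], cfg)
    assert len(fovs) == 3
    for f in fovs:
        pts = f[["x", "y"]].to_numpy()
        assert len(pts) == 20
        np.testing.assert_allclose(pts - pts.mean(0), src - src.mean(0), atol=1e-9)
        assert (f["label"] == 0).all()


def test_training_set_single_source_and_background_fraction():
    rng = np.random.default_rng(3)
    src = rng.normal(0, 10, (30, 2))
    cfg = AugmentConfig(n_pointclouds=10, clusters_per_fov=(2, 4),
                        background_fraction=0.25, fov_size=800.0, seed=1)
    fovs = make_training_set([src], cfg)
    for f in fovs:
        n_bg = (f["label"] == -1).sum()
        assert abs(n_bg / len(f) - 0.25) < 0.05
        assert f["label"].max() >= 1   # at least 2 clusters placed
    with pytest.raises(ValueError):
        make_training_set([], cfg)


def test_extract_clusters_centers_and_drops_background():
    t = simulate_scenario(SimScenario("S8", seed=9))
    clusters = extract_clusters(t)
    assert len(clusters) == 20
    for c in clusters:
        np.testing.assert_allclose(c[["x", "y"]].mean().to_numpy(), 0.0, atol=1e-9)


def test_augment_config_validation():
    with pytest.raises(ValueError):
        AugmentConfig(n_pointclouds=0)
    with pytest.raises(ValueError):
        AugmentConfig(dropout_fraction=1.0)
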