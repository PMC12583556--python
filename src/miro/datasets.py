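"""Synthetic SMLM data generators.

Every dataset used by the pipeline can be produced here: the benchmark
Gaussian scenarios (S2-S10), fluorophore-blinking expansion, C-shaped
and ring-shaped clusters, nuclear-pore-like multiscale structures,
rings of spots, adjacent cluster pairs, and the augmentation machinery
that turns a handful of annotated clusters into large training sets.

All generators return localization tables (:mod:`miro.io` schema) with
coordinates in nm and a ``label`` column where ``-1`` marks background.
Given the same seed they are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import as_rng, substream

__all__ = [
    "SimScenario",
    "AugmentConfig",
    "SCENARIOS",
    "simulate_scenario",
    "apply_blinking",
    "simulate_arc_clusters",
    "simulate_npc",
    "simulate_rings_of_spots",
    "simulate_cluster_pair",
    "make_training_set",
    "extract_clusters",
]


# ---------------------------------------------------------------------------
# Benchmark Gaussian scenarios
# ---------------------------------------------------------------------------

#: Per-scenario cluster groups. Each group is (n_clusters, locs_per_cluster,
#: sd_scale) where the Gaussian sd is ``sd_scale * cluster_sd``; the printed
#: cluster "width" convention maps width w -> sd w/2, so the 25/75 nm widths
#: of scenarios 7 and 9 become sd factors 0.5 and 1.5 on the 25 nm base.
SCENARIOS: dict[str, dict] = {
    "S2": {"groups": [(20, 15, 1.0)], "clustered_fraction": 0.5},
    "S3": {"groups": [(20, 15, 1.0)], "clustered_fraction": 0.2},
    "S4": {"groups": [(20, 5, 1.0)], "clustered_fraction": 0.25},
    "S5": {"groups": [(100, 15, 1.0)], "clustered_fraction": 0.5},
    "S6": {"groups": [(20, 50, 1.0)], "clustered_fraction": 0.5, "aspect": 3.0},
    "S7": {"groups": [(10, 15, 0.5), (10, 15, 1.5)], "clustered_fraction": 0.5},
    "S8": {"groups": [(10, 5, 1.0), (10, 15, 1.0)], "clustered_fraction": 0.5},
    "S9": {"groups": [(10, 15, 0.5), (10, 135, 1.5)], "clustered_fraction": 0.5},
    "S10": {"groups": [(20, 15, 1.0)], "clustered_fraction": 0.5, "gradient": True},
}


@dataclass
class SimScenario:
    """Parameters of one benchmark-style simulation.

    Parameters
    ----------
    scenario_id : str
        One of ``S2``...``S10``.
    fov_size : float
        Side of the square field of view in nm.
    cluster_sd : float
        Base Gaussian standard deviation of a cluster in nm. Scenario
        groups with a printed width scale this value (see ``SCENARIOS``).
    seed : int
        Root seed; identical seeds give bit-identical tables.
    blinking : bool
        If true, expand each molecule into several localizations.
    blink_mean, blink_precision : float
        Mean localizations per molecule and isotropic offset sd (nm)
        used when ``blinking`` is on.
    """

    scenario_id: str
    seed: int = 0
    fov_size: float = 2000.0
    cluster_sd: float = 25.0
    blinking: bool = False
    blink_mean: float = 4.5
    blink_precision: float = 5.0

    def __post_init__(self):
        if self.fov_size <= 0:
            raise ValueError("fov_size must be positive")
        if self.scenario_id not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario_id!r}; expected one of {sorted(SCENARIOS)}"
            )


def _table(x, y, label, **extra) -> pd.DataFrame:
    df = pd.DataFrame({"x": np.asarray(x, float), "y": np.asarray(y, float),
                       "label": np.asarray(label, int)})
    for k, v in extra.items():
        df[k] = v
    return df


def simulate_scenario(scenario: SimScenario | str, seed: int | None = None) -> pd.DataFrame:
    """Simulate one benchmark scenario field of view.

    Clusters are isotropic Gaussians (elliptical with 3:1 aspect for S6)
    whose centers are uniform over the FOV; background is uniform except
    for S10, whose background density ramps linearly from left to right.
    The clustered fraction of the total molecule count follows the
    scenario definition exactly.
    """
    if isinstance(scenario, str):
        scenario = SimScenario(scenario, seed=0 if seed is None else seed)
    spec = SCENARIOS[scenario.scenario_id]
    rng = substream(scenario.seed, f"sim:{scenario.scenario_id}")

    xs, ys, labels = [], [], []
    next_label = 0
    n_clustered = 0
    for n_clusters, n_locs, sd_scale in spec["groups"]:
        sd = sd_scale * scenario.cluster_sd
        centers = rng.uniform(0.0, scenario.fov_size, size=(n_clusters, 2))
        for c in centers:
            if "aspect" in spec:
                a = spec["aspect"]
                # geometric-mean sd preserved: major = sd*sqrt(a), minor = sd/sqrt(a)
                major, minor = sd * math.sqrt(a), sd / math.sqrt(a)
                theta = rng.uniform(0.0, 2 * math.pi)
                u = rng.normal(0.0, major, n_locs)
                v = rng.normal(0.0, minor, n_locs)
                dx = u * math.cos(theta) - v * math.sin(theta)
                dy = u * math.sin(theta) + v * math.cos(theta)
            else:
                dx = rng.normal(0.0, sd, n_locs)
                dy = rng.normal(0.0, sd, n_locs)
            xs.append(c[0] + dx)
            ys.append(c[1] + dy)
            labels.append(np.full(n_locs, next_label))
            next_label += 1
            n_clustered += n_locs

    f = spec["clustered_fraction"]
    n_background = round(n_clustered * (1.0 - f) / f)
    if spec.get("gradient"):
        # left-to-right linear density ramp: p(x) proportional to x
        bx = scenario.fov_size * np.sqrt(rng.uniform(0.0, 1.0, n_background))
    else:
        bx = rng.uniform(0.0, scenario.fov_size, n_background)
    by = rng.uniform(0.0, scenario.fov_size, n_background)
    xs.append(bx)
    ys.append(by)
    labels.append(np.full(n_background, -1))

    table = _table(np.concatenate(xs), np.concatenate(ys), np.concatenate(labels))
    if scenario.blinking:
        table = apply_blinking(
            table, scenario.blink_mean, scenario.blink_precision,
            substream(scenario.seed, "blink"),
        )
    return table


def apply_blinking(table: pd.DataFrame, mean_locs: float, precision: float,
                   seed) -> pd.DataFrame:
    """Expand molecules into multiple localizations (fluorophore blinking).

    Each molecule is replaced by ``1 + Poisson(mean_locs - 1)``
    localizations so every molecule appears at least once and the mean
    count equals ``mean_locs``. Children are offset by isotropic normal
    noise with sd ``precision`` and inherit all label columns.
    """
    if mean_locs <= 0:
        raise ValueError("mean_locs must be positive")
    if precision < 0:
        raise ValueError("precision must be non-negative")
    if len(table) == 0:
        return table.copy()
    rng = as_rng(seed)
    counts = 1 + rng.poisson(mean_locs - 1.0, size=len(table))
    idx = np.repeat(np.arange(len(table)), counts)
    out = table.iloc[idx].reset_index(drop=True)
    noise = rng.normal(0.0, precision, size=(len(out), 2)) if precision > 0 else 0.0
    if precision > 0:
        out["x"] = out["x"].to_numpy() + noise[:, 0]
        out["y"] = out["y"].to_numpy() + noise[:, 1]
    return out


# ---------------------------------------------------------------------------
# Arc-shaped clusters (C shapes and rings)
# ---------------------------------------------------------------------------

def _separated_centers(rng, n: int, fov_size: float, min_separation: float,
                       max_tries: int = 2000) -> np.ndarray:
    """Uniform centers with a minimum pairwise separation.

    Dart throwing with a best-candidate fallback: if no admissible
    position is found within ``max_tries``, the candidate farthest from
    the existing centers is kept, so generation always terminates.
    """
    pts: list[np.ndarray] = []
    for _ in range(n):
        best, best_d = None, -1.0
        for _ in range(max_tries):
            p = rng.uniform(0.0, fov_size, 2)
            d = min((float(np.linalg.norm(p - q)) for q in pts), default=np.inf)
            if d >= min_separation:
                best = p
                break
            if d > best_d:
                best_d, best = d, p
        pts.append(best)
    return np.array(pts)


def simulate_arc_clusters(kind: str, seed: int = 0, fov_size: float = 6400.0,
                          n_clusters_range: tuple[int, int] | None = None,
                          radius: float = 250.0, radial_sd: float = 50.0,
                          locs_range: tuple[int, int] | None = None,
                          background_fraction: float | None = None,
                          min_separation: float | None = None) -> pd.DataFrame:
    """Simulate C-shaped (``kind='c_shape'``) or ring-shaped clusters.

    Localizations are placed on a semicircle (C) or full circle (ring)
    of the given radius with normal radial noise. Defaults follow the
    study conditions: C shapes use 30-60 clusters of 30-60 localizations
    with 6% background; rings use 60-70 clusters of 60-80 localizations
    with 7% background, both in a 6400 nm FOV. ``background_fraction``
    is the background share of the *total* localization count.

    Centers keep a minimum pairwise separation of one structure
    diameter (``2 * radius``) by default — these shapes model disjoint
    supramolecular assemblies, which adjoin but do not interpenetrate;
    pass ``min_separation=0`` for fully unconstrained placement.
    """
    if kind not in ("c_shape", "ring"):
        raise ValueError(f"kind must be 'c_shape' or 'ring', got {kind!r}")
    if radial_sd < 0:
        raise ValueError("radial_sd must be non-negative")
    if kind == "c_shape":
        n_clusters_range = n_clusters_range or (30, 60)
        locs_range = locs_range or (30, 60)
        background_fraction = 0.06 if background_fraction is None else background_fraction
    else:
        n_clusters_range = n_clusters_range or (60, 70)
        locs_range = locs_range or (60, 80)
        background_fraction = 0.07 if background_fraction is None else background_fraction
    if min_separation is None:
        min_separation = 2.0 * radius

    rng = substream(seed, f"arc:{kind}")
    n_clusters = int(rng.integers(n_clusters_range[0], n_clusters_range[1] + 1))
    if min_separation > 0:
        centers = _separated_centers(rng, n_clusters, fov_size, min_separation)
    else:
        centers = rng.uniform(0.0, fov_size, size=(n_clusters, 2))
    xs, ys, labels = [], [], []
    for lab, c in enumerate(centers):
        n = int(rng.integers(locs_range[0], locs_range[1] + 1))
        start = rng.uniform(0.0, 2 * math.pi)
        span = math.pi if kind == "c_shape" else 2 * math.pi
        ang = start + rng.uniform(0.0, span, n)
        r = radius + rng.normal(0.0, radial_sd, n)
        xs.append(c[0] + r * np.cos(ang))
        ys.append(c[1] + r * np.sin(ang))
        labels.append(np.full(n, lab))
    n_clustered = sum(len(a) for a in xs)
    n_background = round(background_fraction / (1.0 - background_fraction) * n_clustered)
    xs.append(rng.uniform(0.0, fov_size, n_background))
    ys.append(rng.uniform(0.0, fov_size, n_background))
    labels.append(np.full(n_background, -1))
    return _table(np.concatenate(xs), np.concatenate(ys), np.concatenate(labels))


# ---------------------------------------------------------------------------
# Nuclear-pore-like multiscale structures
# ---------------------------------------------------------------------------

def _corner_sd(theta_local: np.ndarray, height: float) -> np.ndarray:
    """Center-to-perimeter distance of the corner triangle / 1.8.

    The corner is an isosceles triangle with apex at the structure
    center, height ``height`` along the local +x axis and apex half-angle
    pi/8 (eight corners tile the full circle). Rays start from the
    corner center at ``height / 2`` (the ring radius) on the bisector;
    ``theta_local`` is the ray direction in the local frame.
    """
    half = math.pi / 8.0
    apex = np.array([0.0, 0.0])
    b1 = np.array([height, height * math.tan(half)])
    b2 = np.array([height, -height * math.tan(half)])
    center = np.array([height / 2.0, 0.0])
    verts = [apex, b1, b2]
    d = np.cos(theta_local), np.sin(theta_local)
    dist = np.full(theta_local.shape, np.inf)
    for i in range(3):
        p, q = verts[i], verts[(i + 1) % 3]
        # ray-segment intersection from the corner center along (cos t, sin t)
        ex, ey = q[0] - p[0], q[1] - p[1]
        ox, oy = p[0] - center[0], p[1] - center[1]
        denom = d[0] * (-ey) + d[1] * ex
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (ox * (-ey) + oy * ex) / denom
            s = (d[0] * oy - d[1] * ox) / denom
        ok = (t > 0) & (s >= 0) & (s <= 1)
        dist = np.where(ok & (t < dist), t, dist)
    return dist / 1.8


def sample_npc_corner(n: int, rng, height: float = 100.0):
    """Sample ``n`` localizations for one corner in the local frame.

    Points spread around the corner center — at the ring radius
    ``height / 2`` (50 nm) on the corner bisector — with a direction-
    dependent sd equal to the center-to-perimeter distance of the
    corner triangle divided by 1.8. Along the bisector this gives a
    one-sigma reach from about 20 nm (inward) to about 80 nm (outward)
    from the structure center, the corner's effective radial envelope.
    """
    center = np.array([height / 2.0, 0.0])
    theta = rng.uniform(0.0, 2 * math.pi, n)
    sd = _corner_sd(theta, height)
    r = np.abs(rng.normal(0.0, 1.0, n)) * sd
    return center + np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def simulate_npc(seed: int = 0, fov_size: float = 1250.0,
                 n_structures_range: tuple[int, int] = (5, 9),
                 corner_height: float = 100.0,
                 locs_range: tuple[int, int] = (0, 80),
                 background_fraction: float = 0.03) -> pd.DataFrame:
    """Simulate nuclear-pore-like eightfold-symmetric structures.

    Each structure has 8 corner slots sharing a common vertex; corner
    triangles have height 100 nm (circle radius 50 nm). Per-corner
    localization counts are uniform over ``locs_range`` (corners may be
    empty). The table carries two label levels: ``label`` is the
    structure id and ``sublabel`` a globally unique corner (spot) id.
    """
    rng = substream(seed, "npc")
    n_structures = int(rng.integers(n_structures_range[0], n_structures_range[1] + 1))
    centers = rng.uniform(0.0, fov_size, size=(n_structures, 2))
    xs, ys, labels, sublabels = [], [], [], []
    spot_id = 0
    for lab, c in enumerate(centers):
        phase = rng.uniform(0.0, 2 * math.pi)
        for corner in range(8):
            n = int(rng.integers(locs_range[0], locs_range[1] + 1))
            ang = phase + corner * math.pi / 4.0
            local = sample_npc_corner(n, rng, corner_height)
            rot = np.array([[math.cos(ang), -math.sin(ang)],
                            [math.sin(ang), math.cos(ang)]])
            pts = local @ rot.T + c
            xs.append(pts[:, 0])
            ys.append(pts[:, 1])
            labels.append(np.full(n, lab))
            sublabels.append(np.full(n, spot_id))
            spot_id += 1
    n_clustered = sum(len(a) for a in xs)
    n_background = round(background_fraction / (1.0 - background_fraction) * n_clustered)
    xs.append(rng.uniform(0.0, fov_size, n_background))
    ys.append(rng.uniform(0.0, fov_size, n_background))
    labels.append(np.full(n_background, -1))
    sublabels.append(np.full(n_background, -1))
    return _table(np.concatenate(xs), np.concatenate(ys), np.concatenate(labels),
                  sublabel=np.concatenate(sublabels).astype(int))


def simulate_rings_of_spots(seed: int = 0, fov_size: float = 1250.0,
                            n_rings_range: tuple[int, int] = (40, 60),
                            ring_radius: float = 40.0, spot_sd: float = 15.0,
                            locs_range: tuple[int, int] = (6, 30),
                            symmetry_range: tuple[int, int] = (5, 9),
                            background_fraction: float = 0.015) -> pd.DataFrame:
    """Simulate rings of symmetric Gaussian spots (multiscale benchmark).

    Spots of sd 15 nm carrying 6-30 localizations each are arranged with
    5- to 9-fold symmetry on a circle of radius 40 nm. ``label`` is the
    ring id, ``sublabel`` the globally unique spot id.
    """
    rng = substream(seed, "rings_of_spots")
    n_rings = int(rng.integers(n_rings_range[0], n_rings_range[1] + 1))
    centers = rng.uniform(0.0, fov_size, size=(n_rings, 2))
    xs, ys, labels, sublabels = [], [], [], []
    spot_id = 0
    for lab, c in enumerate(centers):
        fold = int(rng.integers(symmetry_range[0], symmetry_range[1] + 1))
        phase = rng.uniform(0.0, 2 * math.pi)
        for s in range(fold):
            ang = phase + 2 * math.pi * s / fold
            sc = c + ring_radius * np.array([math.cos(ang), math.sin(ang)])
            n = int(rng.integers(locs_range[0], locs_range[1] + 1))
            xs.append(sc[0] + rng.normal(0.0, spot_sd, n))
            ys.append(sc[1] + rng.normal(0.0, spot_sd, n))
            labels.append(np.full(n, lab))
            sublabels.append(np.full(n, spot_id))
            spot_id += 1
    n_clustered = sum(len(a) for a in xs)
    n_background = round(background_fraction / (1.0 - background_fraction) * n_clustered)
    xs.append(rng.uniform(0.0, fov_size, n_background))
    ys.append(rng.uniform(0.0, fov_size, n_background))
    labels.append(np.full(n_background, -1))
    sublabels.append(np.full(n_background, -1))
    return _table(np.concatenate(xs), np.concatenate(ys), np.concatenate(labels),
                  sublabel=np.concatenate(sublabels).astype(int))


def simulate_cluster_pair(distance_in_sigma: float, seed: int = 0,
                          sigma: float = 25.0, mean_locs: float = 90.0) -> pd.DataFrame:
    """Simulate two adjacent Gaussian clusters.

    Both clusters have sd ``sigma`` (25 nm); per-cluster counts are
    geometric on {1, 2, ...} with the stated mean; centers are separated
    by ``distance_in_sigma * sigma`` along x.
    """
    if distance_in_sigma < 0:
        raise ValueError("distance_in_sigma must be non-negative")
    rng = substream(seed, "pair")
    sep = distance_in_sigma * sigma
    xs, ys, labels = [], [], []
    for lab, cx in enumerate((-sep / 2.0, sep / 2.0)):
        n = int(rng.geometric(1.0 / mean_locs))
        xs.append(cx + rng.normal(0.0, sigma, n))
        ys.append(rng.normal(0.0, sigma, n))
        labels.append(np.full(n, lab))
    return _table(np.concatenate(xs), np.concatenate(ys), np.concatenate(labels))


# ---------------------------------------------------------------------------
# Few-shot augmentation
# ---------------------------------------------------------------------------

@dataclass
class AugmentConfig:
    """Augmented-training-set parameters.

    ``n_pointclouds`` FOVs are assembled from randomly selected,
    independently augmented copies of the source clusters. Defaults
    follow the few-shot training recipe: free rotations and reflections,
    mild dropout/addition and jitter, uniform background.
    """

    n_pointclouds: int = 1500
    rotation: bool = True
    reflection: bool = True
    dropout_fraction: float = 0.1
    addition_fraction: float = 0.1
    jitter_sd: float = 2.0
    fov_size: float = 2000.0
    clusters_per_fov: tuple[int, int] = (2, 6)
    background_fraction: float = 0.2
    blinking: bool = False
    blink_mean: float = 4.5
    blink_precision: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.n_pointclouds < 1:
            raise ValueError("n_pointclouds must be >= 1")
        if not (0.0 <= self.dropout_fraction < 1.0):
            raise ValueError("dropout_fraction must be in [0, 1)")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")


def extract_clusters(table: pd.DataFrame) -> list[pd.DataFrame]:
    """Split a labeled table into per-cluster tables centered at origin.

    Background rows are dropped. Each returned table keeps ``sublabel``
    and ``shape_class`` columns when present, with coordinates relative
    to the cluster centroid — the natural input to
    :func:`make_training_set`.
    """
    out = []
    for lab, grp in table[table["label"] >= 0].groupby("label"):
        g = grp.copy()
        g["x"] -= g["x"].mean()
        g["y"] -= g["y"].mean()
        out.append(g.reset_index(drop=True))
    return out


def _augment_cluster(cluster: pd.DataFrame, cfg: AugmentConfig, rng) -> pd.DataFrame:
    pts = cluster[["x", "y"]].to_numpy().copy()
    keep = np.ones(len(pts), bool)
    if cfg.dropout_fraction > 0:
        keep = rng.uniform(size=len(pts)) >= cfg.dropout_fraction
        if not keep.any():
            keep[rng.integers(len(pts))] = True
    g = cluster.loc[keep].reset_index(drop=True)
    pts = pts[keep]
    if cfg.addition_fraction > 0 and len(pts) > 0:
        n_add = int(round(cfg.addition_fraction * len(pts)))
        if n_add:
            src = rng.integers(0, len(pts), n_add)
            extra = g.iloc[src].reset_index(drop=True)
            jitter = rng.normal(0.0, max(cfg.jitter_sd, 1.0), size=(n_add, 2))
            pts = np.vstack([pts, pts[src] + jitter])
            g = pd.concat([g, extra], ignore_index=True)
    if cfg.rotation:
        a = rng.uniform(0.0, 2 * math.pi)
        rot = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
        pts = pts @ rot.T
    if cfg.reflection and rng.uniform() < 0.5:
        pts[:, 0] = -pts[:, 0]
    if cfg.jitter_sd > 0:
        pts = pts + rng.normal(0.0, cfg.jitter_sd, size=pts.shape)
    g["x"], g["y"] = pts[:, 0], pts[:, 1]
    return g


def make_training_set(source_clusters, cfg: AugmentConfig) -> list[pd.DataFrame]:
    """Build an augmented training set from a few annotated clusters.

    Parameters
    ----------
    source_clusters : sequence of DataFrame or (n, 2) arrays
        Representative clusters (coordinates relative to their centers;
        see :func:`extract_clusters`). A single cluster suffices.
    cfg : AugmentConfig

    Returns
    -------
    list of DataFrame
        ``cfg.n_pointclouds`` labeled FOVs. ``label`` enumerates the
        placed copies; ``sublabel``/``shape_class`` columns are carried
        over from the sources (sublabels renumbered per copy).
    """
    if len(source_clusters) == 0:
        raise ValueError("at least one source cluster is required")
    sources = []
    for s in source_clusters:
        if not isinstance(s, pd.DataFrame):
            s = pd.DataFrame(np.asarray(s, float), columns=["x", "y"])
        sources.append(s.reset_index(drop=True))
    rng = substream(cfg.seed, "augment")

    fovs = []
    for _ in range(cfg.n_pointclouds):
        n_clusters = int(rng.integers(cfg.clusters_per_fov[0], cfg.clusters_per_fov[1] + 1))
        parts = []
        next_sub = 0
        for lab in range(n_clusters):
            src = sources[rng.integers(len(sources))]
            g = _augment_cluster(src, cfg, rng)
            center = rng.uniform(0.0, cfg.fov_size, 2)
            g["x"] += center[0]
            g["y"] += center[1]
            g["label"] = lab
            if "sublabel" in g.columns:
                subs = g["sublabel"].to_numpy()
                uniq = {s: next_sub + i for i, s in enumerate(np.unique(subs))}
                g["sublabel"] = [uniq[s] for s in subs]
                next_sub += len(uniq)
            parts.append(g)
        fov = pd.concat(parts, ignore_index=True)
        n_clustered = len(fov)
        f = cfg.background_fraction
        n_bg = round(f / (1.0 - f) * n_clustered) if f > 0 else 0
        if n_bg:
            bg = pd.DataFrame({
                "x": rng.uniform(0.0, cfg.fov_size, n_bg),
                "y": rng.uniform(0.0, cfg.fov_size, n_bg),
                "label": np.full(n_bg, -1),
            })
            if "sublabel" in fov.columns:
                bg["sublabel"] = -1
            if "shape_class" in fov.columns:
                bg["shape_class"] = -1
            fov = pd.concat([fov, bg], ignore_index=True)
        if cfg.blinking:
            fov = apply_blinking(fov, cfg.blink_mean, cfg.blink_precision, rng)
        fovs.append(fov)
    return fovs
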