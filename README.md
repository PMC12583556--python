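# miro-smlm

Graph-neural-network preprocessing that makes density-based clustering
work on hard single-molecule localization microscopy (SMLM) data.

SMLM experiments (STORM/PALM/PAINT) produce point clouds of molecular
positions with nanometre precision. Grouping those localizations into
biological structures — protein nanoclusters, focal adhesions, nuclear
pore complexes — is usually done with DBSCAN, which struggles when
clusters are non-convex (C shapes, rings), adjacent, nested at several
scales, or buried in background. This package implements **MIRO**
(multifunctional integration through relational optimization): a small
recurrent graph network that learns, from as little as one annotated
cluster, a per-localization displacement field that *squeezes* every
cluster toward its center while leaving background untouched. After
squeezing, plain DBSCAN separates structures that it would otherwise
merge, fragment, or miss.

## Method

A field of view becomes a graph: nodes are localizations, edges come
from a Delaunay triangulation filtered at a length threshold δ. Node
features are the absolute entries of the *n* = 5 smallest non-trivial
eigenvectors of the symmetric normalized graph Laplacian
Δ = I − D<sup>−1/2</sup>AD<sup>−1/2</sup> (structural position, no
absolute coordinates); each directed edge carries (‖d<sub>ij</sub>‖,
d<sub>ij</sub>)/s with d<sub>ij</sub> = x<sub>j</sub> − x<sub>i</sub>.
Encoders lift node and edge features to width *H*; a single recurrent
block is applied *K* times:

    f_ij^{k+1} = φ([ũ_i^k, ũ_j^k, f̃_ij^k])        ũ = [v', u],  f̃ = [e', f]
    u_i^{k+1}  = ψ( Σ_{j∈N_i} f_ij^{k+1} )

where φ, ψ are dense + ReLU layers and the hidden state (u, f) starts
at zero. Depth grows the receptive field without adding parameters. A
shared linear decoder turns the hidden node state at *every* step into
a displacement r̂<sub>i</sub><sup>k</sup> (and optionally class
logits). Training minimizes, averaged over steps, nodes and edges,

    L = L_r + L_d [+ L_class]
    L_r = mean_k,i |r̂_i^k − r_i|                  (MAE to the centroid displacement)
    L_d = α · mean_k,(i,j) |d(p̂_i^k, p̂_j^k) − d(p_i, p_j)|
    L_class = β · mean_k,i CE(ĉ_i^k, c_i)

with r<sub>i</sub> = cluster centroid − x<sub>i</sub> (zero for
background) and p = x + r. Giving different steps different targets
(spot centroids before step k*, ring centroids after) yields multiscale
clustering in one forward pass. Few-shot training builds hundreds of
synthetic FOVs from a handful of annotated clusters via rotations,
reflections, dropout/addition, jitter, and random placement.

The evaluation panel implements ARI, an imbalance-robust variant ARI†
(unweighted averages of per-cluster adjusted Wallace indices), AMI,
ARI_c (ARI over truly clustered points only), Hungarian cluster
matching with threshold ξ, the detection Jaccard index
JI_c = TP/(TP+FP+FN), RMSRE_N, RMSE_x,y, convex-hull IoU, the
compression index, and the Dirichlet energy. The network (including
backpropagation through the recurrence) is implemented directly on
numpy arrays.

## Worked example

Few-shot pipeline on simulated C-shaped clusters (radius 250 nm,
radial sd 50 nm, 30–60 clusters per 6400 × 6400 nm² FOV, 6%
background):

```python
from miro.datasets import (AugmentConfig, extract_clusters,
                           make_training_set, simulate_arc_clusters)
from miro.estimators import MiroTransformer
from miro.workflows import benchmark_scenario
from miro.cluster import default_grid

source = simulate_arc_clusters("c_shape", seed=100)    # one labeled FOV
training = make_training_set(extract_clusters(source),
                             AugmentConfig(n_pointclouds=200, fov_size=1600.0,
                                           clusters_per_fov=(1, 3),
                                           background_fraction=0.06, seed=1))
model = MiroTransformer(hidden_dim=64, n_steps=10, epochs=30, delta=250.0,
                        feature_scale=50.0, alpha=1.0, learning_rate=3e-3,
                        random_state=0).fit(training)

test = [simulate_arc_clusters("c_shape", seed=200 + i) for i in range(10)]
report = benchmark_scenario(test, model, optimize_fovs=5,
                            grid=default_grid((10, 100, 10), (3, 30, 3)))
print(report.groupby("method")[["ari", "ari_dagger", "ji_c", "rmsre_n"]].mean())
```

On this configuration the run prints (a few minutes on one CPU):

```
             ari  ari_dagger      ji_c   rmsre_n
method
dbscan  0.765092    0.882441  0.737768  0.481409
miro    0.811885    0.899643  0.900225  0.316901
```

Reading: with its own grid-optimized DBSCAN parameters, the raw data
yields a detection Jaccard of 0.74 — adjacent C shapes get merged and
their sizes overestimated (RMSRE_N 0.48). After squeezing with the
trained model, the same search finds parameters that recover 90% of
the structures with far better size estimates. A shell interface with
`simulate / train / squeeze / cluster / evaluate / benchmark`
subcommands is installed as `miro`.

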