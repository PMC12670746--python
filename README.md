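# spiceist

Subcellular-pattern-integrated cell embedding and clustering for
imaging-based spatial transcriptomics.

## Why

Imaging-based spatial transcriptomics (10x Xenium, CosMx SMI) records the
position of every detected transcript at sub-micron resolution, together
with a segmentation-derived cell assignment. Standard analysis collapses
each cell to a count vector over the gene panel and clusters it like
scRNA-seq — throwing away where transcripts sit *inside* the cell, even
though subcellular RNA localization (nuclear retention, peripheral export,
polarized transport) varies between cell states that can share near-
identical count profiles.

This package implements a graph-autoencoder embedding that uses both
levels of information. For each cell c the transcripts are binned on a
2 µm grid (counts x_{c,g,m} for grid g and gene m), smoothed with a
truncated Gaussian kernel (σ = 3 µm) over the cell's occupied grids, and
L2-normalized over the whole grid × gene block. The cell becomes a graph
G_c whose nodes are its occupied grids with 4-neighbour lattice edges and
these features. A two-block GCN encoder (128 → 64) with a node-wise MLP
decoder is trained with a dual objective

    L = L_recon + α · L_embed ,

where L_recon is the per-element MSE of the node-feature reconstruction
and L_embed the per-element MSE between the mean-pooled 64-D latent
h̄_c and the cell's conventional expression embedding z_c (library-size
normalization to 100 → log1p → per-gene z-scoring → top-64 PCA). Small α
(default 0.25) weights subcellular structure; large α collapses the
embedding onto the expression baseline. Cells are clustered by Louvain on
a 16-nearest-neighbour graph of the embedding at resolutions 0.3–1.8, and
evaluated with silhouette / Calinski–Harabasz / Davies–Bouldin indices,
spatial label assortativity, homogeneity/completeness, and paired
Wilcoxon + Benjamini–Hochberg comparisons across patches.

A first-class simulator generates Xenium-style transcript tables with
ground-truth cell types, subtypes and per-gene localization patterns
(uniform / nuclear / peripheral / polarized), so the whole pipeline is
exercisable without any download. The autoencoder, its gradients and the
Adam optimizer are implemented directly on numpy/scipy arrays; runs are
deterministic given a seed and need only a CPU.

## Worked example

```python
from spiceist import make_separation_fixture, gex_embedding, spiceist_embedding
from spiceist.benchmarks import subtype_ari
from spiceist.clustering import cluster_embedding
from spiceist.metrics import clustering_indices

# 1,000 cells, 30 genes; type T3 splits into two subtypes with identical
# expression programs but opposite localization of ten genes.
table, truth = make_separation_fixture(seed=1)

ids, z = gex_embedding(table, seed=1)                      # expression baseline
_, latents, model = spiceist_embedding(table, alpha=0.25, seed=1)

for name, X in [("GEX", z), ("integrated", latents)]:
    res = cluster_embedding(X, resolutions=[0.6, 0.9], seed=1, cell_ids=ids)
    for r in (0.6, 0.9):
        lab = res.labels[r]
        m = clustering_indices(X, lab)
        print(f"{name:10s} r={r}: {res.n_clusters[r]} clusters  "
              f"subtype ARI {subtype_ari(ids, lab, truth):.2f}  "
              f"ASW {m.asw:.3f}  CHI {m.chi:.1f}  DBI {m.dbi:.3f}")
```

prints (a few minutes on one CPU):

```
GEX        r=0.6: 3 clusters  subtype ARI 0.00  ASW 0.360  CHI 517.4  DBI 1.120
GEX        r=0.9: 3 clusters  subtype ARI 0.00  ASW 0.360  CHI 517.4  DBI 1.120
integrated r=0.6: 3 clusters  subtype ARI 0.00  ASW 0.332  CHI 635.5  DBI 1.204
integrated r=0.9: 4 clusters  subtype ARI 0.21  ASW 0.259  CHI 530.6  DBI 1.540
```

Reading this: the expression baseline recovers the three major types and —
by construction — can never separate the localization-defined subtypes
(restricted ARI 0 at every resolution). The integrated embedding scores a
higher Calinski–Harabasz index on the same data and, from resolution 0.9,
spends its extra granularity on a fourth cluster aligned with the subtype
axis (restricted ARI 0.21): cluster purity stays perfect while
completeness drops — the over-clustering signature of subtype structure.
The split is partial, not clean; `docs/methods.md` discusses why the
per-cell subcellular signal that survives gridding, 3 µm smoothing and
mean pooling separates the subtypes strongly enough to redirect cluster
granularity but not enough for a clean 16-NN Louvain partition.

A thin CLI mirrors the library: `spiceist simulate | ingest | gex | train |
cluster | evaluate` (see `spiceist --help`).

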