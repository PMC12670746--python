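# Methods

## The problem

Imaging-based spatial transcriptomics (10x Xenium, CosMx SMI) detects
individual transcripts of a targeted gene panel in situ, giving each
transcript a sub-micron position and a cell assignment from segmentation.
Conventional clustering collapses each cell to a gene-count vector and so
discards where transcripts sit *inside* the cell — even though two cells
with indistinguishable count profiles can differ systematically in
subcellular RNA localization (nuclear retention, peripheral/ER export,
polarized transport). This package embeds cells using both levels of
information and clusters the result.

## Pipeline

1. **Patching and filtering.** A slide is optionally split into an R x C
   lattice of equal rectangles (half-open bins, final row/column closed);
   patches without any cell-assigned transcript are dropped. Each patch is
   treated as an independent dataset. Cells with total transcript count
   strictly greater than 10 are retained.

2. **Subcellular gridding.** Each cell's transcripts are tallied on a
   square lattice of side `grid_size` (default 2 µm; transcript (x, y)
   lands in grid `(floor(x/s), floor(y/s))`). Only occupied grids are kept.
   Counts are smoothed per cell with a truncated, normalized Gaussian
   kernel over the cell's occupied grid centres (sigma = 1.5 x grid size =
   3 µm, truncated at 3 sigma); the kernel normalizes by the sum of weights
   so constant fields are preserved and edge grids are unbiased. The
   smoothed block is divided by its Frobenius norm (summing squares over
   grids *and* genes), so every cell presents a unit-norm feature block.
   Unoccupied grids inside the cell footprint are not imputed as zeros: the
   segmentation mask is not part of the minimal input, and the kernel's
   normalization makes the occupied-grid reading self-consistent.

3. **Cell-level embedding (GEX).** Per-cell gene totals are normalized to a
   library size of 100, log1p-transformed, z-scored per gene with the
   population (ddof = 0) standard deviation (constant genes dropped, no
   clipping), and projected onto the top K = min(64, kept genes, cells - 1)
   principal components, fitted per patch. Component signs follow the
   largest-|loading|-positive convention so results are solver-independent.
   This embedding z_c is simultaneously the GEX clustering baseline and the
   autoencoder's cell-level target.

4. **Cell graphs.** Each cell becomes a graph: nodes are its occupied
   grids (ordered by (gy, gx)), edges join grids that differ by exactly one
   step in one lattice direction (4-neighbour; no diagonals). Node features
   are the normalized subcellular block; z_c is attached as the cell-level
   target. Disconnected components stay in one graph — the GCN treats them
   independently and pooling spans all nodes.

5. **Graph autoencoder.** Encoder: `Drop(ReLU(BN(GCN_128(x))))` followed by
   `Drop(BN(GCN_64(·)))`; the latent block is *not* rectified (see Design
   choices). GCN propagation uses `D^-1/2 (A+I) D^-1/2`. Decoder: node-wise
   `FC(Drop(ReLU(BN(FC_128(·)))))` back to M genes. Dropout p = 0.2; batch
   norm is over all nodes of a mini-batch with running statistics
   (momentum 0.1) used at inference. The loss is

       L = L_recon + alpha * L_embed,

   with L_recon the squared reconstruction error averaged per cell over its
   nodes x genes and then over cells, and L_embed the squared error between
   the mean-pooled 64-D latent h̄_c and z_c, averaged per element over the K
   target dimensions and over cells. Both terms are per-element MSE losses,
   which keeps their scales commensurate — the subcellular block is
   unit-norm, so a sum-over-dimensions embedding term would outweigh the
   reconstruction term by roughly three orders of magnitude and reduce the
   method to a rectified re-embedding of z. alpha defaults to 0.25
   (subcellular-weighted).

6. **Training.** Adam (lr 1e-3), cells split 80:20 once per run; each of up
   to 50 epochs draws 32 random mini-batches of 32 cells; validation
   iterates fixed-order batches without shuffling and uses the total loss.
   Early stopping: an epoch "improves" when its validation loss beats the
   best by more than 1e-4; after 3 consecutive non-improving epochs
   training stops, and the checkpoint of the last improving epoch is kept.
   One seed governs the split, batch sampling, dropout and initialization.

7. **Clustering and evaluation.** Any embedding (pooled latents or GEX
   PCs) is turned into an unweighted, union-symmetrized 16-nearest-
   neighbour graph (Euclidean; ties broken by cell index) and partitioned
   with Louvain at resolutions 0.3–1.8. Evaluation: average silhouette
   width, Calinski–Harabasz and Davies–Bouldin indices in the embedding
   space (singleton-cluster silhouettes are 0); Newman's discrete attribute
   assortativity of labels over a spatial 16-NN graph (undefined — returned
   as None — when one label covers all cells); homogeneity/completeness
   against reference labels (zero-entropy conventions give 1); per-patch
   effect sizes as ln(mean_a / mean_b) (natural log, ratio of means); and
   paired two-sided Wilcoxon signed-rank tests with Benjamini–Hochberg
   adjustment. The signed-rank null is evaluated exactly (dynamic
   programming over midranks, so ties are handled) for up to 25 non-zero
   differences and by normal approximation with continuity correction
   above; all-zero differences report p = 1 by convention, and fewer than
   5 pairs report p = NaN.

## Design choices

- **Unrectified latent block.** The cell-level target z_c is a signed PCA
  score vector, and the limiting behaviour of the dual objective (alpha
  large => h̄_c -> z_c, so integrated clustering collapses onto GEX
  clustering) is only attainable if the pooled latent can take negative
  values. A rectified latent can at best reach max(z, 0), which merges
  cell types whose embeddings differ in the negative half-space. The latent
  block therefore keeps its batch norm — which balances per-dimension
  variance so fine subcellular structure is not drowned by the dominant
  cell-level directions — and its dropout, but omits the ReLU.
- **Target-rank masking.** With fewer than 64 kept genes the PCA target has
  rank K < 64. The embedding loss is evaluated on the K constrained
  dimensions only; the remaining latent dimensions carry no target and are
  shaped by the reconstruction objective alone. (Zero-padding the target
  instead would actively regress those dimensions to zero, deleting the
  capacity in which subcellular structure lives. On panels of 64+ genes,
  the paper regime, the two readings coincide.)
- **Validation loss for early stopping** is the total L, not L_recon alone.
- **"32 batches"** is read as 32 mini-batches per epoch; the cells per
  mini-batch (32 by default) are configurable. **"Iterations"** in the
  early-stopping rule are read as epochs, since validation is evaluated
  once per epoch.
- **Union (not mutual) kNN symmetrization**, unweighted edges; Louvain (not
  Leiden) with an exposed seed, communities renumbered by smallest member.
- **Grid indexing** is 0-based with half-open bins; a transcript exactly on
  a boundary goes to the higher bin.

## Synthetic data

The simulator emulates a Xenium-style experiment at desk scale. Cells are
non-overlapping disks (dart-throwing placement) with radius ~ N(10, 1.2²)
µm, truncated at 3 µm — 20 µm diameter, typical of tumour epithelium.
Per-cell gene counts are negative binomial (type-specific mean vector,
dispersion theta = 10), giving realistic overdispersion. Each gene in each
(sub)type carries a localization pattern: uniform over the disk, nuclear
(inner 40 % of the radius), peripheral (outer annulus from 70 % of the
radius) or polarized (half-disk along a per-cell random axis), blended with
uniform via a contrast delta in [0, 1] (a transcript follows its pattern
with probability delta). Subtypes share a parent type and an *identical*
expression program, differing only in localization — the regime where
cell-level counts are uninformative by construction. Optional transcript
mis-assignment to a nearby cell emulates segmentation spillover.

Two canonical fixtures:

- **Separation fixture** — 1,000 cells, 30 genes, types T1/T2/T3 (30/30/40
  %), T3 split into T3a/T3b with identical programs; genes 1–10 (T3's
  high-expression block, mean 12 per gene) are nuclear in T3a and
  peripheral in T3b at delta = 0.8; everything else uniform; mixed spatial
  arrangement on a 1,040 µm slide (~200 transcripts per cell).
- **Expression-only fixture** — 600 cells, 30 genes, four types with
  distinct programs, all localization uniform (delta = 0), used to verify
  the large-alpha limit.

What the simulator does *not* model: nuclei as stained compartments,
irregular cell shapes, optical crowding, z-stacks, segmentation errors
beyond label spillover, or spatial neighbourhood expression structure.
Passing tests therefore demonstrate that the implementation realizes the
method's mechanics and its core separation behaviour under controlled
conditions — not that the method succeeds on any particular tissue.

## Problem sizes and numerical notes

Benchmarks run at 600–1,000 cells with a 30-gene panel and 3 replicate
seeds, sizes chosen so each end-to-end experiment completes in minutes on
one CPU while leaving the method's behaviour clearly measurable. Batch-norm
epsilon is 1e-5; Adam uses (0.9, 0.999, 1e-8); weights are Glorot-uniform.
All randomness flows from one integer seed per run (numpy Generator).
Degenerate inputs fail loudly: all-zero feature blocks, zero-total cells,
single-cluster metric requests and non-finite losses raise errors rather
than propagating silently.

## Known limitations

- Dense per-cell grid x gene blocks: fine for hundreds of genes; a 5,000-
  plex panel at scale would want sparse blocks and mini-batched gridding.
- The hand-rolled network is CPU-only by design; wall-clock scales roughly
  linearly in total node count.
- Louvain on the union-symmetrized unweighted kNN graph can emit small
  clusters at high resolution; singleton silhouette handling (score 0)
  matters there.
- Spatial assortativity assumes 2-D coordinates; no 3-D neighbour graphs.
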