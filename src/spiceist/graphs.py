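"""Per-cell grid graphs and disjoint-union batching.

Each cell becomes a small graph whose nodes are its occupied 2 µm grids,
connected to their four lattice neighbours (up/down/left/right, no
diagonals).  Node features are the smoothed, L2-normalized subcellular
profiles; the cell-level PCA vector z_c rides along as the target of the
autoencoder's second loss term.  Batches are disjoint unions with a
node -> cell index map so per-cell pooling is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .gridding import CellGrid


@dataclass
class CellGraph:
    """One cell's grid graph: nodes, 4-neighbour edges, features and target."""

    cell_id: str
    nodes: np.ndarray          # (n, 2) int grid indices (gx, gy), sorted by (gy, gx)
    edges: np.ndarray          # (E, 2) int node-index pairs, i < j
    node_features: np.ndarray  # (n, M)
    cell_target: np.ndarray    # (K,)
    _adj_norm: sp.csr_matrix | None = field(default=None, repr=False, compare=False)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def adj_norm(self) -> sp.csr_matrix:
        """Symmetric-normalized adjacency with self-loops: D^-1/2 (A+I) D^-1/2."""
        if self._adj_norm is None:
            n = self.n_nodes
            if len(self.edges):
                i, j = self.edges[:, 0], self.edges[:, 1]
                rows = np.r_[i, j, np.arange(n)]
                cols = np.r_[j, i, np.arange(n)]
            else:
                rows = cols = np.arange(n)
            data = np.ones(len(rows))
            a = sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
            deg = np.asarray(a.sum(axis=1)).ravel()
            d_inv_sqrt = 1.0 / np.sqrt(deg)
            self._adj_norm = sp.csr_matrix(a.multiply(d_inv_sqrt[:, None]).multiply(d_inv_sqrt[None, :]))
        return self._adj_norm


def build_cell_graph(
    features: np.ndarray, grid: CellGrid, target: np.ndarray
) -> CellGraph:
    """Assemble a cell's graph from its feature block, grids and target.

    An edge joins two occupied grids iff their indices differ by exactly 1 in
    one coordinate and 0 in the other.  Node order follows the grid order
    (sorted by (gy, gx)), so the graph is independent of record order.
    """
    features = np.asarray(features, dtype=float)
    if features.shape[0] != grid.n_grids:
        raise ValueError(
            f"feature rows ({features.shape[0]}) do not match occupied grids ({grid.n_grids})"
        )
    index_of = {(int(gx), int(gy)): i for i, (gx, gy) in enumerate(grid.indices)}
    edges = []
    for (gx, gy), i in index_of.items():
        for nb in ((gx + 1, gy), (gx, gy + 1)):
            j = index_of.get(nb)
            if j is not None:
                edges.append((min(i, j), max(i, j)))
    edges_arr = np.array(sorted(edges), dtype=int).reshape(-1, 2)
    return CellGraph(
        cell_id=grid.cell_id,
        nodes=grid.indices.copy(),
        edges=edges_arr,
        node_features=features,
        cell_target=np.asarray(target, dtype=float),
    )


@dataclass
class BatchedGraphs:
    """Disjoint union of cell graphs with exact per-cell pooling support."""

    cell_ids: list[str]
    X: np.ndarray              # (N, M) stacked node features
    adj: sp.csr_matrix         # (N, N) block-diagonal normalized adjacency
    cell_index: np.ndarray     # (N,) node -> position in cell_ids
    pool: sp.csr_matrix        # (C, N) mean-pooling operator
    targets: np.ndarray        # (C, latent_dim) zero-padded cell targets
    n_target_dims: int         # K: leading latent dims constrained by targets
    node_sizes: np.ndarray     # (C,) nodes per cell

    @property
    def n_nodes(self) -> int:
        return self.X.shape[0]

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


def batch_graphs(graphs: list[CellGraph], latent_dim: int = 64) -> BatchedGraphs:
    """Stack graphs into one disjoint union.

    Targets shorter than ``latent_dim`` are zero-padded for storage, but
    ``n_target_dims`` records the true target rank K so the pooled-latent
    loss can be restricted to the K constrained dimensions; the remaining
    latent dimensions are shaped by the reconstruction objective alone.
    """
    if not graphs:
        raise ValueError("cannot batch an empty list of graphs")
    sizes = np.array([g.n_nodes for g in graphs])
    X = np.vstack([g.node_features for g in graphs])
    adj = sp.block_diag([g.adj_norm for g in graphs], format="csr")
    cell_index = np.repeat(np.arange(len(graphs)), sizes)
    N = int(sizes.sum())
    pool = sp.csr_matrix(
        (1.0 / sizes[cell_index], (cell_index, np.arange(N))), shape=(len(graphs), N)
    )
    targets = np.zeros((len(graphs), latent_dim))
    n_target_dims = 0
    for i, g in enumerate(graphs):
        k = len(g.cell_target)
        if k > latent_dim:
            raise ValueError(f"cell target has {k} dims, more than latent_dim={latent_dim}")
        targets[i, :k] = g.cell_target
        n_target_dims = max(n_target_dims, k)
    return BatchedGraphs(
        cell_ids=[g.cell_id for g in graphs],
        X=X,
        adj=adj,
        cell_index=cell_index,
        pool=pool,
        targets=targets,
        n_target_dims=n_target_dims,
        node_sizes=sizes,
    )
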