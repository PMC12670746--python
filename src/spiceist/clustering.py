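"""Cell clustering: 16-nearest-neighbour graph plus Louvain communities.

Any cell embedding (the pooled autoencoder latent or the GEX principal
components) is turned into an unweighted, union-symmetrized kNN graph on
Euclidean distance, then partitioned with the Louvain modularity algorithm
at one or more resolutions.  Both embedding choices share all code after
this point, so metric differences isolate the embedding itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array

DEFAULT_RESOLUTIONS = (0.3, 0.6, 0.9, 1.2, 1.5, 1.8)


def knn_graph(embedding: np.ndarray, k: int = 16) -> nx.Graph:
    """Union-symmetrized k-nearest-neighbour graph on Euclidean distance.

    Each cell contributes edges to its k nearest other cells; ties are
    broken by cell index (argsort is stable), making the graph
    deterministic.  After union symmetrization every node has degree >= k.
    """
    X = check_array(np.asarray(embedding, dtype=float))
    C = X.shape[0]
    if C <= k:
        raise ValueError(f"need more than k={k} cells, got {C}")
    d = cdist(X, X)
    np.fill_diagonal(d, np.inf)
    nbrs = np.argsort(d, axis=1, kind="stable")[:, :k]
    g = nx.Graph()
    g.add_nodes_from(range(C))
    rows = np.repeat(np.arange(C), k)
    cols = nbrs.ravel()
    g.add_edges_from(zip(rows.tolist(), cols.tolist()))
    return g


@dataclass
class ClusterResult:
    """Louvain labels per resolution, with cluster counts."""

    cell_ids: list[str]
    labels: dict[float, np.ndarray] = field(default_factory=dict)
    n_clusters: dict[float, int] = field(default_factory=dict)
    seed: int = 0

    def as_mapping(self, resolution: float) -> dict[str, str]:
        lab = self.labels[resolution]
        return {cid: str(int(l)) for cid, l in zip(self.cell_ids, lab)}


def louvain_cluster(g: nx.Graph, resolution: float, seed: int = 0) -> np.ndarray:
    """Louvain community labels at the given resolution, seeded.

    Labels are contiguous integers from 0; communities are numbered by
    their smallest member index so relabelling is deterministic.
    """
    comms = nx.community.louvain_communities(g, resolution=resolution, seed=seed)
    comms = sorted(comms, key=min)
    labels = np.empty(g.number_of_nodes(), dtype=int)
    for lab, members in enumerate(comms):
        labels[list(members)] = lab
    return labels


def cluster_embedding(
    embedding: np.ndarray,
    resolutions: Sequence[float] = DEFAULT_RESOLUTIONS,
    k: int = 16,
    seed: int = 0,
    cell_ids: Sequence[str] | None = None,
) -> ClusterResult:
    """Build the kNN graph once and run Louvain at each resolution."""
    embedding = np.asarray(embedding, dtype=float)
    if cell_ids is None:
        cell_ids = [str(i) for i in range(embedding.shape[0])]
    result = ClusterResult(cell_ids=list(cell_ids), seed=seed)
    if not len(resolutions):
        return result
    g = knn_graph(embedding, k=k)
    for r in resolutions:
        labels = louvain_cluster(g, resolution=r, seed=seed)
        result.labels[r] = labels
        result.n_clusters[r] = int(labels.max()) + 1
    return result


class LouvainClusterer(ClusterMixin, BaseEstimator):
    """kNN-graph Louvain clustering as a scikit-learn style estimator.

    Parameters
    ----------
    n_neighbors : int, default 16
        Neighbours per cell in the graph.
    resolution : float, default 1.0
        Louvain modularity resolution (higher -> more clusters).
    random_state : int, default 0
        Seed for the Louvain algorithm.
    """

    def __init__(self, n_neighbors: int = 16, resolution: float = 1.0, random_state: int = 0):
        self.n_neighbors = n_neighbors
        self.resolution = resolution
        self.random_state = random_state

    def fit(self, X, y=None):
        g = knn_graph(X, k=self.n_neighbors)
        self.labels_ = louvain_cluster(g, resolution=self.resolution, seed=self.random_state)
        self.n_clusters_ = int(self.labels_.max()) + 1
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
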