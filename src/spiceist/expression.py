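"""Cell-level expression features and their 64-component PCA projection.

This is the conventional single-cell pipeline applied to imaging-ST counts:
per-cell gene totals are normalized to a fixed library size of 100,
log1p-transformed, z-scored per gene, and projected onto the top principal
components (64 by default).  The resulting vector z_c is both the cell-level
target of the graph autoencoder and the embedding of the GEX baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_array, check_is_fitted

from .gridding import GridCountTensor


@dataclass
class CellCounts:
    """Cells x genes count matrix at a given transform stage (raw | lognorm)."""

    cell_ids: list[str]
    matrix: np.ndarray
    panel: list[str]
    stage: str = "raw"

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]


@dataclass
class CellEmbedding:
    """Per-cell projection scores plus the fitted embedder that produced them."""

    cell_ids: list[str]
    z: np.ndarray
    embedder: "ExpressionEmbedder"

    @property
    def n_components(self) -> int:
        return self.z.shape[1]


def aggregate_cell_counts(grid: GridCountTensor) -> CellCounts:
    """Sum each cell's grid counts over grids: u_{c,m} = sum_g x_{c,g,m}."""
    cell_ids = grid.cell_ids
    M = len(grid.panel)
    matrix = np.zeros((len(cell_ids), M), dtype=float)
    for i, cid in enumerate(cell_ids):
        matrix[i] = grid.cells[cid].counts.sum(axis=0)
    return CellCounts(cell_ids=cell_ids, matrix=matrix, panel=list(grid.panel), stage="raw")


def lognormalize(counts: CellCounts, target_sum: float = 100.0) -> CellCounts:
    """Library-size normalize to ``target_sum`` then log1p.

    u_log = ln(1 + target_sum * u / rowsum).  Rows with zero total are an
    error; the count filter upstream should have removed them.
    """
    if counts.stage != "raw":
        raise ValueError(f"expected raw counts, got stage {counts.stage!r}")
    totals = counts.matrix.sum(axis=1)
    if np.any(totals <= 0):
        bad = [counts.cell_ids[i] for i in np.flatnonzero(totals <= 0)[:5]]
        raise ValueError(f"cells with zero total count cannot be normalized: {bad}")
    lognorm = np.log1p(target_sum * counts.matrix / totals[:, None])
    return CellCounts(
        cell_ids=list(counts.cell_ids), matrix=lognorm, panel=list(counts.panel), stage="lognorm"
    )


class ExpressionEmbedder(TransformerMixin, BaseEstimator):
    """Z-score genes and project cells onto the top principal components.

    Parameters
    ----------
    n_components : int, default 64
        Upper bound on the number of components; the fitted rank is
        ``min(n_components, kept genes, n_cells - 1)``.
    random_state : int or None
        Seed for the randomized SVD solver (only used for wide problems).

    Scaling uses the population (ddof=0) standard deviation; genes with zero
    variance are dropped with a warning.  Component signs follow the
    convention that each component's largest-magnitude loading is positive,
    which makes the projection reproducible across solvers.
    """

    def __init__(self, n_components: int = 64, random_state: int | None = None):
        self.n_components = n_components
        self.random_state = random_state

    def fit(self, X, y=None):
        self._fit(X)
        return self

    def _fit(self, X) -> np.ndarray:
        X = check_array(X, dtype=float)
        C, M = X.shape
        if C < 2:
            raise ValueError("need at least 2 cells to fit a projection")
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)  # population sd
        keep = sd > 0
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} constant gene(s) before scaling", stacklevel=2
            )
        if not keep.any():
            raise ValueError("all genes are constant; nothing to project")
        self.keep_mask_ = keep
        self.scale_ = sd[keep]
        Xs = (X[:, keep] - self.mean_[keep]) / self.scale_
        k = min(self.n_components, int(keep.sum()), C - 1)
        solver = "full" if max(C, int(keep.sum())) <= 1000 else "randomized"
        pca = PCA(n_components=k, svd_solver=solver, random_state=self.random_state)
        scores = pca.fit_transform(Xs)
        # sign convention: largest-|loading| entry of each component positive
        comp = pca.components_
        flip = np.sign(comp[np.arange(k), np.argmax(np.abs(comp), axis=1)])
        flip[flip == 0] = 1.0
        self.components_ = comp * flip[:, None]
        self.explained_variance_ = pca.explained_variance_
        self.n_components_ = k
        self.n_features_in_ = M
        return scores * flip[None, :]

    def fit_transform(self, X, y=None):
        return self._fit(X)

    def transform(self, X):
        check_is_fitted(self, "components_")
        X = check_array(X, dtype=float)
        Xs = (X[:, self.keep_mask_] - self.mean_[self.keep_mask_]) / self.scale_
        return Xs @ self.components_.T

    def scaled(self, X) -> np.ndarray:
        """The z-scored matrix (kept genes only) used for the projection."""
        check_is_fitted(self, "components_")
        X = check_array(X, dtype=float)
        return (X[:, self.keep_mask_] - self.mean_[self.keep_mask_]) / self.scale_


def scale_and_project(
    counts: CellCounts, k: int = 64, seed: int | None = None
) -> CellEmbedding:
    """Fit :class:`ExpressionEmbedder` on lognorm counts and return scores z_c."""
    if counts.stage != "lognorm":
        raise ValueError(f"expected lognorm counts, got stage {counts.stage!r}")
    emb = ExpressionEmbedder(n_components=k, random_state=seed)
    z = emb.fit_transform(counts.matrix)
    return CellEmbedding(cell_ids=list(counts.cell_ids), z=z, embedder=emb)
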