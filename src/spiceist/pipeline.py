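"""End-to-end embedding pipelines: the subcellular-integrated path and the
conventional expression (GEX) baseline.

Both paths start from the same transcript table and count>10 cell filter
and share all clustering/evaluation code downstream, so differences in
cluster structure are attributable to the embedding alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autoencoder import GraphAutoencoder
from .expression import (
    CellEmbedding,
    aggregate_cell_counts,
    lognormalize,
    scale_and_project,
)
from .gridding import GriddingConfig, assign_grids, gaussian_smooth, l2_normalize
from .graphs import CellGraph, build_cell_graph
from .io import TranscriptTable, filter_cells


@dataclass
class PreparedData:
    """Everything derived from one transcript table before model training."""

    cell_ids: list[str]
    graphs: list[CellGraph]
    gex: CellEmbedding


def prepare(
    table: TranscriptTable,
    min_total: int = 10,
    grid_size: float = 2.0,
    sigma: float | None = None,
    n_components: int = 64,
    seed: int | None = 0,
) -> PreparedData:
    """Filter cells, grid/smooth/normalize subcellular features, compute the
    cell-level PCA embedding, and assemble per-cell graphs."""
    cells = filter_cells(table, min_total=min_total)
    if len(cells) < 2:
        raise ValueError(f"only {len(cells)} cells pass the count>{min_total} filter")
    cfg = GriddingConfig(grid_size=grid_size, sigma=sigma)
    grid = assign_grids(table, cells, cfg)
    feats = l2_normalize(gaussian_smooth(grid, cfg))
    counts = aggregate_cell_counts(grid)
    gex = scale_and_project(lognormalize(counts), k=n_components, seed=seed)
    graphs = [
        build_cell_graph(feats.values[cid], grid.cells[cid], gex.z[i])
        for i, cid in enumerate(gex.cell_ids)
    ]
    return PreparedData(cell_ids=list(gex.cell_ids), graphs=graphs, gex=gex)


def gex_embedding(
    table: TranscriptTable,
    min_total: int = 10,
    grid_size: float = 2.0,
    n_components: int = 64,
    seed: int | None = 0,
) -> tuple[list[str], np.ndarray]:
    """The GEX baseline: per-cell counts -> lognorm -> z-score -> top PCs."""
    prep = prepare(table, min_total=min_total, grid_size=grid_size,
                   n_components=n_components, seed=seed)
    return prep.cell_ids, prep.gex.z


def spiceist_embedding(
    table: TranscriptTable,
    alpha: float = 0.25,
    min_total: int = 10,
    grid_size: float = 2.0,
    sigma: float | None = None,
    epochs: int = 50,
    seed: int = 0,
    **train_kwargs,
) -> tuple[list[str], np.ndarray, GraphAutoencoder]:
    """The full subcellular-integrated pipeline.

    Returns (cell ids, pooled 64-D latents, fitted model).  ``train_kwargs``
    pass through to :class:`~spiceist.autoencoder.GraphAutoencoder`.
    """
    prep = prepare(table, min_total=min_total, grid_size=grid_size, sigma=sigma, seed=seed)
    model = GraphAutoencoder(alpha=alpha, epochs=epochs, random_state=seed, **train_kwargs)
    model.fit(prep.graphs)
    latents = model.transform(prep.graphs)
    return prep.cell_ids, latents, model
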