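"""Transcript-table input/output, patch splitting and cell filtering.

Imaging-based spatial transcriptomics platforms (10x Xenium, CosMx SMI)
export one row per detected transcript: its x/y position in µm, the gene it
maps to, and the cell it was assigned to by segmentation.  This module reads
those exports into :class:`TranscriptTable`, splits whole slides into
rectangular patches that are analysed independently, and applies the
total-count cell filter used before any per-cell computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Sentinel cell id for transcripts the segmentation did not assign to a cell.
UNASSIGNED = "__unassigned__"

#: Column mapping for the Xenium "transcripts" export dialect.
XENIUM_COLUMNS = {
    "x": "x_location",
    "y": "y_location",
    "gene": "feature_name",
    "cell_id": "cell_id",
}

_REQUIRED = ("x", "y", "gene", "cell_id")


@dataclass
class TranscriptTable:
    """Per-transcript records plus the gene panel and slide bounds.

    ``data`` has columns ``x``, ``y`` (µm), ``gene`` and ``cell_id``;
    unassigned transcripts carry :data:`UNASSIGNED`.  ``panel`` is the
    ordered list of the M genes the platform can detect (a gene may have
    zero detected transcripts).  ``bounds`` is ``(xmin, ymin, xmax, ymax)``.
    """

    data: pd.DataFrame
    panel: list[str]
    bounds: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.panel) < 1:
            raise ValueError("panel must contain at least one gene")
        if len(set(self.panel)) != len(self.panel):
            raise ValueError("panel contains duplicate gene names")
        missing = [c for c in _REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"transcript data lacks columns {missing}")
        if len(self.data):
            unknown = set(self.data["gene"]) - set(self.panel)
            if unknown:
                raise ValueError(f"records reference genes outside the panel: {sorted(unknown)[:5]}")
            xmin, ymin, xmax, ymax = self.bounds
            x = self.data["x"].to_numpy()
            y = self.data["y"].to_numpy()
            if x.min() < xmin or x.max() > xmax or y.min() < ymin or y.max() > ymax:
                raise ValueError("transcript coordinates fall outside the stated bounds")

    @property
    def n_records(self) -> int:
        return len(self.data)

    @property
    def n_genes(self) -> int:
        return len(self.panel)

    def assigned(self) -> pd.DataFrame:
        """Records assigned to a cell (drops the UNASSIGNED sentinel)."""
        return self.data[self.data["cell_id"] != UNASSIGNED]

    def cell_counts(self) -> pd.Series:
        """Total assigned transcript count per cell id."""
        return self.assigned()["cell_id"].value_counts()


@dataclass
class CellLabels:
    """Mapping cell id -> label (reference cell type or cluster id)."""

    mapping: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.mapping)

    def __getitem__(self, cell_id: str) -> str:
        return self.mapping[cell_id]


def load_transcripts(
    path: str | Path,
    format: str | None = None,
    column_map: Mapping[str, str] | None = None,
    unassigned_codes: Sequence[str] = ("-1", "UNASSIGNED", ""),
    panel: Sequence[str] | None = None,
    bounds: tuple[float, float, float, float] | None = None,
) -> TranscriptTable:
    """Read a vendor transcript export (CSV or parquet) into a TranscriptTable.

    ``column_map`` maps the canonical names ``x``/``y``/``gene``/``cell_id``
    to the file's column names; defaults to the Xenium dialect.  Rows whose
    cell assignment matches one of ``unassigned_codes`` are retained with the
    :data:`UNASSIGNED` sentinel.  ``panel`` defaults to the distinct genes in
    the file (sorted); ``bounds`` default to the data's bounding box.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"transcript file not found: {path}")
    if format is None:
        format = "parquet" if path.suffix in {".parquet", ".pq"} else "csv"
    if format == "csv":
        raw = pd.read_csv(path)
    elif format == "parquet":
        raw = pd.read_parquet(path)
    else:
        raise ValueError(f"unknown transcript format {format!r} (expected 'csv' or 'parquet')")

    cmap = dict(XENIUM_COLUMNS)
    if column_map:
        cmap.update(column_map)
    for key in _REQUIRED:
        if cmap[key] not in raw.columns:
            raise ValueError(
                f"column {cmap[key]!r} (for {key!r}) missing from {path.name}; "
                f"available: {list(raw.columns)}"
            )
    data = pd.DataFrame(
        {
            "x": raw[cmap["x"]].astype(float),
            "y": raw[cmap["y"]].astype(float),
            "gene": raw[cmap["gene"]].astype(str),
            "cell_id": raw[cmap["cell_id"]].astype(str),
        }
    )
    data.loc[data["cell_id"].isin([str(c) for c in unassigned_codes]), "cell_id"] = UNASSIGNED
    if panel is None:
        panel = sorted(data["gene"].unique())
    if bounds is None:
        if len(data) == 0:
            raise ValueError(f"{path.name} holds no records and no bounds were given")
        bounds = (
            float(data["x"].min()),
            float(data["y"].min()),
            float(data["x"].max()),
            float(data["y"].max()),
        )
    return TranscriptTable(data=data.reset_index(drop=True), panel=list(panel), bounds=bounds)


def split_patches(table: TranscriptTable, n_rows: int, n_cols: int) -> list[TranscriptTable]:
    """Split the slide bounding box into an ``n_rows`` x ``n_cols`` lattice.

    Intervals are half-open ``[lo, hi)`` except the final row/column, which
    is closed so boundary transcripts are never lost.  Each record lands in
    exactly one patch.  Patches containing no cell-assigned transcript are
    dropped.  Returned in row-major order (row index major, column minor).
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("n_rows and n_cols must be >= 1")
    xmin, ymin, xmax, ymax = table.bounds
    width = (xmax - xmin) / n_cols
    height = (ymax - ymin) / n_rows

    x = table.data["x"].to_numpy()
    y = table.data["y"].to_numpy()
    if width > 0:
        col = np.minimum((np.floor((x - xmin) / width)).astype(int), n_cols - 1)
    else:
        col = np.zeros(len(x), dtype=int)
    if height > 0:
        row = np.minimum((np.floor((y - ymin) / height)).astype(int), n_rows - 1)
    else:
        row = np.zeros(len(y), dtype=int)

    patches: list[TranscriptTable] = []
    for r in range(n_rows):
        for c in range(n_cols):
            mask = (row == r) & (col == c)
            sub = table.data[mask]
            if not (sub["cell_id"] != UNASSIGNED).any():
                continue
            pb = (
                xmin + c * width,
                ymin + r * height,
                xmax if c == n_cols - 1 else xmin + (c + 1) * width,
                ymax if r == n_rows - 1 else ymin + (r + 1) * height,
            )
            patches.append(
                TranscriptTable(data=sub.reset_index(drop=True), panel=list(table.panel), bounds=pb)
            )
    return patches


def filter_cells(table: TranscriptTable, min_total: int = 10) -> set[str]:
    """Cell ids whose total assigned transcript count is strictly > ``min_total``."""
    counts = table.cell_counts()
    return set(counts.index[counts > min_total])


# ---------------------------------------------------------------------------
# TSV persistence for embeddings and label maps
# ---------------------------------------------------------------------------

def save_embedding(cell_ids: Sequence[str], matrix: np.ndarray, path: str | Path) -> None:
    """Write a cells x features matrix as TSV (cell_id index, header row)."""
    matrix = np.asarray(matrix, dtype=float)
    df = pd.DataFrame(matrix, index=list(cell_ids))
    df.index.name = "cell_id"
    df.columns = [f"f{j}" for j in range(matrix.shape[1])]
    try:
        df.to_csv(path, sep="\t", float_format="%.15g")
    except OSError as exc:  # pragma: no cover - depends on filesystem
        raise OSError(f"failed to write embedding to {path}: {exc}") from exc


def load_embedding(path: str | Path) -> tuple[list[str], np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"embedding file not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col="cell_id")
    return [str(i) for i in df.index], df.to_numpy(dtype=float)


def save_labels(labels: Mapping[str, str] | CellLabels, path: str | Path) -> None:
    """Write a cell_id -> label map as two-column TSV."""
    mapping = labels.mapping if isinstance(labels, CellLabels) else dict(labels)
    df = pd.DataFrame({"cell_id": list(mapping.keys()), "label": list(mapping.values())})
    try:
        df.to_csv(path, sep="\t", index=False)
    except OSError as exc:  # pragma: no cover
        raise OSError(f"failed to write labels to {path}: {exc}") from exc


def load_labels(path: str | Path) -> CellLabels:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"cell_id", "label"}.issubset(df.columns):
        raise ValueError(f"{path} must have columns cell_id and label")
    if df["cell_id"].duplicated().any():
        raise ValueError(f"{path} assigns a cell id more than one label")
    return CellLabels(dict(zip(df["cell_id"], df["label"])))
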