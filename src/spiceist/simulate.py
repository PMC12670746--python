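"""Synthetic imaging-based spatial transcriptomics with known ground truth.

Cells are non-overlapping disks scattered on a square slide.  Each cell
type carries an expression program (negative-binomial mean counts per gene,
shared dispersion) and, per gene, a subcellular localization pattern:

``uniform``
    transcripts anywhere in the cell footprint;
``nuclear``
    concentrated in the inner 40% of the radius (a nucleus stand-in);
``peripheral``
    an annulus covering the outer 30% of the radius (membrane/periphery);
``polarized``
    a half-disk on a per-cell random orientation.

A localization contrast delta in [0, 1] blends each pattern with uniform:
a transcript follows the pattern with probability delta.  Subtypes are cell
types that share a parent type label and an identical expression program
but differ in localization - the regime in which cell-level expression
cannot distinguish them while subcellular patterns can.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import TranscriptTable

NUCLEAR_RADIUS_FRACTION = 0.4
PERIPHERAL_INNER_FRACTION = 0.7

PATTERNS = ("uniform", "nuclear", "peripheral", "polarized")


@dataclass
class CellTypeSpec:
    """One (sub)type: its parent type label, abundance, program, localization."""

    name: str
    parent: str
    proportion: float
    program: np.ndarray              # (M,) mean counts per gene
    localization: list[str]          # (M,) pattern name per gene

    def __post_init__(self) -> None:
        self.program = np.asarray(self.program, dtype=float)
        if np.any(self.program < 0):
            raise ValueError(f"type {self.name}: program means must be nonnegative")
        bad = set(self.localization) - set(PATTERNS)
        if bad:
            raise ValueError(f"type {self.name}: unknown localization pattern(s) {bad}")


@dataclass
class SimConfig:
    """Full description of one simulated slide."""

    n_cells: int
    slide_size: float
    panel: list[str]
    cell_types: list[CellTypeSpec]
    cell_radius_mean: float = 10.0
    cell_radius_sd: float = 1.2
    dispersion: float = 10.0           # negative-binomial size parameter
    localization_contrast: float = 0.8  # delta; 0 => subtypes statistically identical
    arrangement: str = "mixed"          # or "compartmentalized"
    misassignment_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.localization_contrast <= 1.0:
            raise ValueError("localization_contrast must be in [0, 1]")
        if self.arrangement not in ("mixed", "compartmentalized"):
            raise ValueError("arrangement must be 'mixed' or 'compartmentalized'")
        if not 0.0 <= self.misassignment_rate < 1.0:
            raise ValueError("misassignment_rate must be in [0, 1)")
        for t in self.cell_types:
            if len(t.program) != len(self.panel) or len(t.localization) != len(self.panel):
                raise ValueError(f"type {t.name}: program/localization length != panel size")


@dataclass
class GroundTruth:
    """Per-cell truth: type and subtype labels, centre, radius."""

    table: pd.DataFrame  # columns cell_id, type, subtype, x, y, radius

    def type_labels(self) -> dict[str, str]:
        return dict(zip(self.table["cell_id"], self.table["type"]))

    def subtype_labels(self) -> dict[str, str]:
        return dict(zip(self.table["cell_id"], self.table["subtype"]))


def _place_cells(cfg: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Dart-throwing placement of non-overlapping disks; raises if infeasible."""
    L = cfg.slide_size
    centers = np.zeros((cfg.n_cells, 2))
    radii = np.zeros(cfg.n_cells)
    bin_size = 2.0 * (cfg.cell_radius_mean + 4 * cfg.cell_radius_sd)
    grid: dict[tuple[int, int], list[int]] = {}
    placed = 0
    max_tries = 300 * cfg.n_cells
    for _ in range(max_tries):
        if placed == cfg.n_cells:
            break
        r = max(3.0, rng.normal(cfg.cell_radius_mean, cfg.cell_radius_sd))
        c = rng.uniform(r, L - r, size=2)
        bx, by = int(c[0] // bin_size), int(c[1] // bin_size)
        ok = True
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for j in grid.get((bx + dx, by + dy), ()):
                    if np.hypot(*(centers[j] - c)) < radii[j] + r:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            centers[placed] = c
            radii[placed] = r
            grid.setdefault((bx, by), []).append(placed)
            placed += 1
    if placed < cfg.n_cells:
        raise RuntimeError(
            f"could only place {placed}/{cfg.n_cells} non-overlapping cells; "
            "enlarge the slide or shrink the cells"
        )
    return centers, radii


def _type_assignment(cfg: SimConfig, rng: np.random.Generator, centers: np.ndarray) -> np.ndarray:
    """Exact largest-remainder type composition, mixed or in spatial strips."""
    props = np.array([t.proportion for t in cfg.cell_types], dtype=float)
    props = props / props.sum()
    counts = np.floor(props * cfg.n_cells).astype(int)
    remainder = cfg.n_cells - counts.sum()
    order = np.argsort(-(props * cfg.n_cells - counts), kind="stable")
    counts[order[:remainder]] += 1
    assignment = np.repeat(np.arange(len(cfg.cell_types)), counts)
    if cfg.arrangement == "mixed":
        return assignment[rng.permutation(cfg.n_cells)]
    # compartmentalized: contiguous vertical strips ordered by x
    return assignment[np.argsort(np.argsort(centers[:, 0], kind="stable"), kind="stable")]


def _sample_positions(
    n: int, pattern: str, center: np.ndarray, radius: float, phi: float,
    delta: float, rng: np.random.Generator,
) -> np.ndarray:
    """Transcript positions inside the disk, pattern blended with uniform."""
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    u = rng.random(n)
    r = radius * np.sqrt(u)  # uniform over the disk
    if pattern != "uniform" and delta > 0:
        use = rng.random(n) < delta
        if pattern == "nuclear":
            r = np.where(use, NUCLEAR_RADIUS_FRACTION * radius * np.sqrt(u), r)
        elif pattern == "peripheral":
            a2 = PERIPHERAL_INNER_FRACTION**2
            r = np.where(use, radius * np.sqrt(a2 + (1.0 - a2) * u), r)
        elif pattern == "polarized":
            half = phi + rng.uniform(-np.pi / 2, np.pi / 2, size=n)
            theta = np.where(use, half, theta)
    return center + np.stack([r * np.cos(theta), r * np.sin(theta)], axis=1)


def simulate(cfg: SimConfig) -> tuple[TranscriptTable, GroundTruth]:
    """Generate one slide: a transcript table plus the ground truth.

    Deterministic given ``cfg.seed``.  With ``misassignment_rate`` > 0, that
    fraction of transcripts keeps its position but is re-assigned to a
    nearby cell, mimicking segmentation spillover.
    """
    rng = np.random.default_rng(cfg.seed)
    centers, radii = _place_cells(cfg, rng)
    type_idx = _type_assignment(cfg, rng, centers)
    phis = rng.uniform(0.0, 2.0 * np.pi, size=cfg.n_cells)  # polarization axes
    M = len(cfg.panel)
    theta = cfg.dispersion

    frames = []
    cell_ids = [f"cell_{i:05d}" for i in range(cfg.n_cells)]
    for i in range(cfg.n_cells):
        spec = cfg.cell_types[type_idx[i]]
        mu = spec.program
        with np.errstate(divide="ignore"):
            p = theta / (theta + mu)
        counts = np.where(mu > 0, rng.negative_binomial(theta, np.minimum(p, 1.0)), 0)
        total = int(counts.sum())
        if total == 0:
            continue
        xs = np.empty((total, 2))
        genes = np.empty(total, dtype=object)
        pos = 0
        for m in np.flatnonzero(counts):
            n_m = int(counts[m])
            xs[pos : pos + n_m] = _sample_positions(
                n_m, spec.localization[m], centers[i], radii[i], phis[i],
                cfg.localization_contrast, rng,
            )
            genes[pos : pos + n_m] = cfg.panel[m]
            pos += n_m
        frames.append(
            pd.DataFrame({"x": xs[:, 0], "y": xs[:, 1], "gene": genes, "cell_id": cell_ids[i]})
        )
    data = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["x", "y", "gene", "cell_id"]
    )

    if cfg.misassignment_rate > 0 and len(data):
        flip = rng.random(len(data)) < cfg.misassignment_rate
        if flip.any():
            d2 = ((centers[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
            np.fill_diagonal(d2, np.inf)
            nearest = np.argsort(d2, axis=1, kind="stable")[:, :3]
            idx_of = {cid: i for i, cid in enumerate(cell_ids)}
            src = data.loc[flip, "cell_id"].map(idx_of).to_numpy()
            pick = nearest[src, rng.integers(0, 3, size=len(src))]
            data.loc[flip, "cell_id"] = [cell_ids[j] for j in pick]

    # clip to slide bounds (patterns never exceed the footprint, but be safe)
    L = cfg.slide_size
    data["x"] = data["x"].clip(0.0, L)
    data["y"] = data["y"].clip(0.0, L)
    table = TranscriptTable(data=data, panel=list(cfg.panel), bounds=(0.0, 0.0, L, L))
    truth = GroundTruth(
        table=pd.DataFrame(
            {
                "cell_id": cell_ids,
                "type": [cfg.cell_types[t].parent for t in type_idx],
                "subtype": [cfg.cell_types[t].name for t in type_idx],
                "x": centers[:, 0],
                "y": centers[:, 1],
                "radius": radii,
            }
        )
    )
    return table, truth


# ---------------------------------------------------------------------------
# canonical fixtures
# ---------------------------------------------------------------------------

def _block_program(levels: Sequence[float], block: int = 10) -> np.ndarray:
    return np.repeat(np.asarray(levels, dtype=float), block)


def separation_config(seed: int = 0) -> SimConfig:
    """Configuration behind :func:`make_separation_fixture`."""
    panel = [f"g{i:02d}" for i in range(1, 31)]
    uniform = ["uniform"] * 30
    nuclear_first = ["nuclear"] * 10 + ["uniform"] * 20
    peripheral_first = ["peripheral"] * 10 + ["uniform"] * 20
    types = [
        CellTypeSpec("T1", "T1", 0.3, _block_program([4, 12, 4]), uniform),
        CellTypeSpec("T2", "T2", 0.3, _block_program([4, 4, 12]), uniform),
        CellTypeSpec("T3a", "T3", 0.2, _block_program([12, 4, 4]), nuclear_first),
        CellTypeSpec("T3b", "T3", 0.2, _block_program([12, 4, 4]), peripheral_first),
    ]
    return SimConfig(
        n_cells=1000,
        slide_size=1040.0,
        panel=panel,
        cell_types=types,
        localization_contrast=0.8,
        arrangement="mixed",
        seed=seed,
    )


def make_separation_fixture(seed: int = 0) -> tuple[TranscriptTable, GroundTruth]:
    """The canonical localization-separation slide.

    1,000 cells, 30 genes, three types; type T3 splits into subtypes T3a and
    T3b with identical expression programs but opposite localization of the
    first ten genes (nuclear vs peripheral, contrast 0.8).  Cell-level
    counts cannot distinguish T3a from T3b; subcellular patterns can.
    """
    return simulate(separation_config(seed))


def alpha_limit_config(seed: int = 0) -> SimConfig:
    """Slide whose types differ only at cell level (all-uniform localization)."""
    panel = [f"g{i:02d}" for i in range(1, 31)]
    uniform = ["uniform"] * 30
    programs = [
        _block_program([14, 3, 3]),
        _block_program([3, 14, 3]),
        _block_program([3, 3, 14]),
        _block_program([8, 8, 1]),
    ]
    types = [
        CellTypeSpec(f"T{i + 1}", f"T{i + 1}", 0.25, prog, uniform)
        for i, prog in enumerate(programs)
    ]
    return SimConfig(
        n_cells=600,
        slide_size=810.0,
        panel=panel,
        cell_types=types,
        localization_contrast=0.0,
        arrangement="mixed",
        seed=seed,
    )


def make_alpha_limit_fixture(seed: int = 0) -> tuple[TranscriptTable, GroundTruth]:
    """600 cells, 30 genes, four types with distinct programs, no localization."""
    return simulate(alpha_limit_config(seed))
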