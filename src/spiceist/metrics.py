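"""Quantitative evaluation of cell clusterings.

Embedding-space validity indices (average silhouette width, the
Calinski-Harabasz index, the Davies-Bouldin index), Newman's discrete
attribute assortativity of cluster labels over a spatial 16-NN graph,
entropy-based homogeneity/completeness against reference cell types,
log-mean-ratio effect sizes across patches, and paired Wilcoxon
signed-rank comparison with Benjamini-Hochberg correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats
from sklearn import metrics as skm
from statsmodels.stats.multitest import multipletests

from .clustering import knn_graph
from .io import CellLabels


@dataclass
class ClusterIndices:
    asw: float
    chi: float
    dbi: float


def clustering_indices(embedding: np.ndarray, labels: Sequence[int]) -> ClusterIndices:
    """ASW, CHI and DBI of a labelling in the embedding space.

    Higher ASW/CHI and lower DBI mean tighter, better-separated clusters.
    Silhouette widths of singleton clusters are 0 (Louvain can emit tiny
    clusters).  Undefined for a single cluster.
    """
    embedding = np.asarray(embedding, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("clustering indices undefined for k=1 cluster")
    asw = float(skm.silhouette_score(embedding, labels))
    chi = float(skm.calinski_harabasz_score(embedding, labels))
    dbi = float(skm.davies_bouldin_score(embedding, labels))
    return ClusterIndices(asw=asw, chi=chi, dbi=dbi)


def spatial_assortativity(
    cell_xy: np.ndarray, labels: Sequence, k: int = 16
) -> float | None:
    """Newman's attribute assortativity of labels over a spatial kNN graph.

    High values mean clusters occupy spatially compact regions; values near
    zero mean clusters are spatially intermixed.  Undefined (returns None)
    when every cell carries the same label.
    """
    labels = list(labels)
    if len(set(labels)) < 2:
        return None
    g = knn_graph(np.asarray(cell_xy, dtype=float), k=k)
    nx.set_node_attributes(g, {i: lab for i, lab in enumerate(labels)}, "label")
    coeff = nx.attribute_assortativity_coefficient(g, "label")
    if not math.isfinite(coeff):
        return None
    return float(coeff)


def homogeneity_completeness(
    labels: Mapping[str, str] | Sequence,
    reference: CellLabels | Mapping[str, str] | Sequence,
) -> tuple[float, float]:
    """Cluster purity (homogeneity) and class integrity (completeness).

    h = 1 - H(ref | clusters)/H(ref); c = 1 - H(clusters | ref)/H(clusters);
    both are 1 by convention when the conditioning entropy is zero.  High
    homogeneity with low completeness is the over-clustering signature: a
    reference type split across several clusters.

    Accepts either aligned label sequences or cell_id -> label mappings
    (evaluated on the shared cell ids, error if none).
    """
    if isinstance(reference, CellLabels):
        reference = reference.mapping
    if isinstance(labels, Mapping) or isinstance(reference, Mapping):
        if not (isinstance(labels, Mapping) and isinstance(reference, Mapping)):
            raise TypeError("give both labellings as mappings, or both as sequences")
        common = sorted(set(labels) & set(reference))
        if not common:
            raise ValueError("labellings share no cell ids")
        pred = [labels[c] for c in common]
        ref = [reference[c] for c in common]
    else:
        pred, ref = list(labels), list(reference)
        if len(pred) != len(ref):
            raise ValueError("labellings have different lengths")
    h = float(skm.homogeneity_score(ref, pred))
    c = float(skm.completeness_score(ref, pred))
    return h, c


def log_mean_ratio(index_a: Sequence[float], index_b: Sequence[float]) -> float:
    """ln(mean(a) / mean(b)) across paired patches (natural log, ratio of means)."""
    a, b = np.asarray(index_a, dtype=float), np.asarray(index_b, dtype=float)
    if len(a) != len(b) or len(a) == 0:
        raise ValueError("index lists must be the same nonzero length")
    ma, mb = a.mean(), b.mean()
    if ma <= 0 or mb <= 0:
        raise ValueError("log mean ratio requires positive means")
    return float(np.log(ma / mb))


@dataclass
class PairedComparison:
    statistic: float
    pvalue: float
    pvalue_adjusted: float
    n: int
    stars: str


def _stars(p: float) -> str:
    if not math.isfinite(p):
        return "na"
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 1e-2:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def _exact_signed_rank_pvalue(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p for W+ given the |difference| ranks (midranks allowed).

    Enumerates the null distribution of W+ = sum of ranks with positive sign
    by dynamic programming over doubled ranks (so midranks become integers);
    each sign is +/- with probability 1/2 under the null.
    """
    r2 = np.round(2 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    w2 = int(round(2 * w_plus))
    lo = dist[: w2 + 1].sum()
    hi = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(lo, hi)))


def wilcoxon_signed_rank(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped.  The exact null distribution is used for
    n <= 25 remaining pairs (ties handled with midranks); the normal
    approximation with continuity correction is used above.  All-zero
    differences give p = 1.0 by convention; fewer than 5 pairs gives
    p = nan (not computable at that sample size).  The statistic is W+,
    the rank sum of positive differences.
    """
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired samples must have equal length")
    diff = a - b
    if np.all(diff == 0):
        return 0.0, 1.0
    if len(a) < 5:
        return math.nan, math.nan
    nonzero = diff[diff != 0]
    ranks = stats.rankdata(np.abs(nonzero))
    w_plus = float(ranks[nonzero > 0].sum())
    if len(nonzero) <= 25:
        return w_plus, _exact_signed_rank_pvalue(ranks, w_plus)
    res = stats.wilcoxon(nonzero, alternative="two-sided", method="approx", correction=True)
    return float(res.statistic), float(res.pvalue)


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Step-up BH-adjusted p-values (nan entries pass through unadjusted)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, math.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def paired_compare(
    family: Sequence[tuple[Sequence[float], Sequence[float]]],
) -> list[PairedComparison]:
    """Wilcoxon signed-rank per pair, BH-adjusted across the family.

    Each family entry is a pair of per-patch metric lists (e.g. one
    clustering index for two methods across patches).
    """
    stats_p = [wilcoxon_signed_rank(a, b) for a, b in family]
    adj = benjamini_hochberg([p for _, p in stats_p])
    return [
        PairedComparison(
            statistic=s, pvalue=p, pvalue_adjusted=float(q), n=len(a), stars=_stars(float(q))
        )
        for (s, p), q, (a, b) in zip(stats_p, adj, family)
    ]
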