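"""Independent brute-force reference implementations used by the tests.

Everything here is written as plain scalar/loop code straight from the
textbook definitions, deliberately sharing no code with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def smooth_oracle(centers: np.ndarray, counts: np.ndarray, sigma: float, trunc: float) -> np.ndarray:
    """Scalar evaluation of truncated-normalized Gaussian smoothing."""
    n, m = counts.shape
    out = np.zeros((n, m))
    for i in range(n):
        wsum = 0.0
        acc = np.zeros(m)
        for j in range(n):
            d = math.dist(centers[i], centers[j])
            if d <= trunc:
                w = math.exp(-(d**2) / (2 * sigma**2))
                wsum += w
                acc += w * counts[j]
        out[i] = acc / wsum
    return out


def silhouette_oracle(X: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width; singleton clusters contribute 0."""
    n = len(X)
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    vals = []
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            vals.append(0.0)
            continue
        a = sum(d[i, j] for j in same) / len(same)
        b = math.inf
        for lab in set(labels) - {labels[i]}:
            other = [j for j in range(n) if labels[j] == lab]
            b = min(b, sum(d[i, j] for j in other) / len(other))
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


def chi_oracle(X: np.ndarray, labels: np.ndarray) -> float:
    """Calinski-Harabasz: [tr(B)/(k-1)] / [tr(W)/(n-k)]."""
    n = len(X)
    labs = sorted(set(labels))
    k = len(labs)
    mean = X.mean(axis=0)
    tr_b = tr_w = 0.0
    for lab in labs:
        pts = X[labels == lab]
        c = pts.mean(axis=0)
        tr_b += len(pts) * float(((c - mean) ** 2).sum())
        tr_w += float(((pts - c) ** 2).sum())
    return (tr_b / (k - 1)) / (tr_w / (n - k))


def dbi_oracle(X: np.ndarray, labels: np.ndarray) -> float:
    """Davies-Bouldin: mean over clusters of max_j (S_i+S_j)/d_ij."""
    labs = sorted(set(labels))
    cents = [X[labels == lab].mean(axis=0) for lab in labs]
    scatter = [
        float(np.mean(np.sqrt(((X[labels == lab] - c) ** 2).sum(axis=1))))
        for lab, c in zip(labs, cents)
    ]
    vals = []
    for i in range(len(labs)):
        worst = 0.0
        for j in range(len(labs)):
            if i == j:
                continue
            d = math.dist(cents[i], cents[j])
            worst = max(worst, (scatter[i] + scatter[j]) / d)
        vals.append(worst)
    return float(np.mean(vals))


def homogeneity_completeness_oracle(ref, pred) -> tuple[float, float]:
    """Conditional-entropy definitions computed from scratch."""
    n = len(ref)

    def entropy(labels):
        h = 0.0
        for lab in set(labels):
            p = sum(1 for x in labels if x == lab) / n
            h -= p * math.log(p)
        return h

    def cond_entropy(a, b):  # H(a | b)
        h = 0.0
        for lb in set(b):
            idx = [i for i in range(n) if b[i] == lb]
            pb = len(idx) / n
            for la in set(a):
                joint = sum(1 for i in idx if a[i] == la) / n
                if joint > 0:
                    h -= joint * math.log(joint / pb)
        return h

    h_ref, h_pred = entropy(ref), entropy(pred)
    hom = 1.0 if h_ref == 0 else 1.0 - cond_entropy(ref, pred) / h_ref
    com = 1.0 if h_pred == 0 else 1.0 - cond_entropy(pred, ref) / h_pred
    return hom, com


def assortativity_oracle(edges, labels) -> float:
    """Newman's discrete assortativity from the mixing matrix, by hand."""
    cats = sorted(set(labels))
    idx = {c: i for i, c in enumerate(cats)}
    e = np.zeros((len(cats), len(cats)))
    for u, v in edges:
        e[idx[labels[u]], idx[labels[v]]] += 1
        e[idx[labels[v]], idx[labels[u]]] += 1
    e /= e.sum()
    a = e.sum(axis=1)
    b = e.sum(axis=0)
    return float((np.trace(e) - a @ b) / (1 - a @ b))


def signed_rank_exact_oracle(diffs: np.ndarray) -> float:
    """Two-sided exact signed-rank p by full enumeration of sign patterns."""
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(diffs))
    n = len(diffs)
    w_obs = float(ranks[diffs > 0].sum())
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.array(ws)
    lo = np.mean(ws <= w_obs)
    hi = np.mean(ws >= w_obs)
    return float(min(1.0, 2 * min(lo, hi)))


def bh_oracle(ps):
    """Step-up Benjamini-Hochberg by hand."""
    m = len(ps)
    order = np.argsort(ps)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top, i in enumerate(order[::-1]):
        rank = m - rank_from_top
        val = min(prev, ps[i] * m / rank)
        adj[i] = val
        prev = val
    return adj
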