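"""Independent brute-force oracles used to cross-check the implementation.

Each function here recomputes a quantity from first principles (explicit
rank formulas, exhaustive pairwise enumeration, naive agglomeration) so
tests compare two genuinely different routes to the same answer.
"""

from __future__ import annotations

import itertools

import numpy as np


def midranks(values: np.ndarray) -> np.ndarray:
    """Mid-ranks computed by explicit enumeration (1-based)."""
    v = np.asarray(values, dtype=float)
    ranks = np.empty(v.size)
    for i, x in enumerate(v):
        less = np.sum(v < x)
        equal = np.sum(v == x)
        ranks[i] = less + (equal + 1) / 2.0
    return ranks


def brute_force_auc(pos, neg) -> float:
    """AUC as the fraction of (positive, negative) pairs won, ties 1/2."""
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def brute_force_kruskal(groups) -> float:
    """Kruskal–Wallis H from explicit mid-ranks with tie correction."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = midranks(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts ** 3 - counts) / (n ** 3 - n)
    return h / tie if tie > 0 else 0.0


def brute_force_spearman(x, y) -> float:
    """Pearson correlation of explicitly computed mid-ranks."""
    rx, ry = midranks(np.asarray(x)), midranks(np.asarray(y))
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def upgma_oracle(points: np.ndarray) -> list[float]:
    """Merge heights of naive average-linkage clustering (Euclidean).

    Clusters are merged greedily at the minimum mean pairwise
    point-to-point distance; returns the sequence of merge heights.
    """
    pts = np.asarray(points, dtype=float)
    clusters = [[i] for i in range(len(pts))]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = np.mean([np.linalg.norm(pts[i] - pts[j])
                         for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return heights


def ols_predictions(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares fitted values with an intercept, via lstsq."""
    A = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return A @ coef
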