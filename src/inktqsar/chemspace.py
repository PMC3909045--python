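"""Chemical-space analysis of the compound × descriptor matrix.

Descriptor sets computed in bulk contain many constant columns (a feature
absent from every molecule in the set); these are pruned first.  The
remaining matrix is autoscaled (zero mean, unit variance per descriptor —
the chemometrics "UV scaling" convention) and summarised two ways:
principal-component score plots, and average-linkage (UPGMA)
agglomerative clustering with Euclidean distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

__all__ = ["PruneResult", "PCAResult", "Dendrogram", "prune_constant_descriptors",
           "autoscale", "pca_scores", "hca_average_linkage"]


class PruneResult(NamedTuple):
    matrix: pd.DataFrame
    removed: list


def prune_constant_descriptors(matrix: pd.DataFrame, tol: float = 1e-12) -> PruneResult:
    """Drop descriptors whose variance is ≤ tol; column order is preserved.

    The default tolerance absorbs floating-point noise on genuinely
    constant columns.  Removing every column is an error.
    """
    if matrix.shape[1] == 0:
        raise ValueError("empty descriptor matrix")
    variances = matrix.var(axis=0, ddof=1)
    keep = variances > tol
    if not keep.any():
        raise ValueError("all descriptor columns are constant at this tolerance")
    removed = [c for c in matrix.columns if not keep[c]]
    return PruneResult(matrix.loc[:, keep], removed)


def autoscale(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Unit-variance scaling; returns (scaled, means, stds). Constant columns
    are left centered but unscaled (std set to 1)."""
    means = matrix.mean(axis=0)
    stds = matrix.std(axis=0, ddof=1).replace(0.0, 1.0)
    return (matrix - means) / stds, means, stds


@dataclass
class PCAResult:
    scores: pd.DataFrame            # compounds × t(1..k)
    loadings: pd.DataFrame          # descriptors × p(1..k)
    explained_variance_fraction: np.ndarray

    def score_plot_frame(self) -> pd.DataFrame:
        """First two score vectors, ready for a t(1)/t(2) scatter."""
        return self.scores.iloc[:, :2]


def pca_scores(matrix: pd.DataFrame, n_components: int = 2,
               scale: bool = True) -> PCAResult:
    """Principal-component decomposition of the (auto)scaled matrix via SVD.

    Deterministic sign convention: within each component the loading of
    largest magnitude is made positive.  Score vectors are mutually
    orthogonal; explained-variance fractions are non-increasing.
    """
    n, p = matrix.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(f"n_components must be in [1, {min(n - 1, p)}], "
                         f"got {n_components}")
    if scale:
        X, _, _ = autoscale(matrix)
    else:
        X = matrix - matrix.mean(axis=0)
    U, s, Vt = np.linalg.svd(X.to_numpy(dtype=float), full_matrices=False)
    # sign convention for reproducibility across BLAS builds
    for j in range(n_components):
        pivot = np.argmax(np.abs(Vt[j]))
        if Vt[j, pivot] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    comp = [f"t({j + 1})" for j in range(n_components)]
    scores = pd.DataFrame(U[:, :n_components] * s[:n_components],
                          index=matrix.index, columns=comp)
    loadings = pd.DataFrame(Vt[:n_components].T, index=matrix.columns,
                            columns=[f"p({j + 1})" for j in range(n_components)])
    explained = (s ** 2) / np.sum(s ** 2)
    return PCAResult(scores=scores, loadings=loadings,
                     explained_variance_fraction=explained[:n_components])


@dataclass
class Dendrogram:
    """Agglomerative clustering result.

    ``merges`` is the standard linkage matrix: each row
    (node_a, node_b, height, size) merges two clusters; leaves are
    0..n−1, merge i creates node n+i.  Average linkage is monotone, so
    heights are non-decreasing.
    """

    merges: np.ndarray
    leaf_labels: list
    metric: str

    @property
    def leaf_order(self) -> list:
        return [self.leaf_labels[i] for i in leaves_list(self.merges)]

    def merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.merges,
                            columns=["node_a", "node_b", "height", "size"])

    def to_newick(self) -> str:
        """Newick string with branch lengths = parent height − child height."""
        n = len(self.leaf_labels)
        heights = {i: 0.0 for i in range(n)}
        children = {}
        for i, (a, b, h, _) in enumerate(self.merges):
            node = n + i
            heights[node] = float(h)
            children[node] = (int(a), int(b))

        def render(node: int, parent_h: float) -> str:
            if node < n:
                label = str(self.leaf_labels[node]).replace(" ", "_")
                return f"{label}:{parent_h - 0.0:.10g}"
            a, b = children[node]
            h = heights[node]
            return f"({render(a, h)},{render(b, h)}):{parent_h - h:.10g}"

        root = n + len(self.merges) - 1
        a, b = children[root]
        h = heights[root]
        return f"({render(a, h)},{render(b, h)});"


def hca_average_linkage(matrix: pd.DataFrame, metric: str = "euclidean",
                        standardize: bool = True) -> Dendrogram:
    """Average-linkage (UPGMA) hierarchical clustering of compounds.

    Distances are Euclidean on the autoscaled matrix by default;
    ``metric="sqeuclidean"`` is accepted.  The merge height between two
    clusters is the mean of all their pairwise point distances.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 compounds to cluster")
    if metric not in ("euclidean", "sqeuclidean"):
        raise ValueError(f"unsupported metric {metric!r}")
    X = autoscale(matrix)[0] if standardize else matrix
    dists = pdist(X.to_numpy(dtype=float), metric=metric)
    Z = linkage(dists, method="average")
    return Dendrogram(merges=Z, leaf_labels=list(matrix.index), metric=metric)
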