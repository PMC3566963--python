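"""Multivariate views of community profiles: PCA and hierarchical clustering.

PCA treats samples as observations and features (at whatever hierarchy
level the table was aggregated to) as variables. The matrix is centered —
optionally standardized — and decomposed by singular values; explained
variance fractions equal the eigenvalue fractions of the sample covariance
matrix. Components carry a deterministic sign: the largest-magnitude
loading of each component is positive. Centering only is the default, since
unit-variance scaling inflates the noise of rare features.

Hierarchical clustering is agglomerative from the full pairwise distance
matrix (Euclidean or 1 - Pearson correlation) with single, complete or
average (UPGMA) linkage via Lance-Williams updates. Ties in the minimum
inter-cluster distance are broken toward the pair with the lowest original
cluster indices, making the merge sequence fully deterministic. The merge
list follows the usual convention: clusters 0..n-1 are the leaves and merge
i creates cluster n+i; the leaf order is the dendrogram's left-to-right
traversal with the earlier-created subcluster first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .abundance import AbundanceTable
from .errors import UsageError, ValidationError

__all__ = [
    "OrdinationResult",
    "ClusteringResult",
    "pca",
    "linkage_matrix",
    "leaf_order",
    "hierarchical_cluster",
]


# ---------------------------------------------------------------------------
# PCA


@dataclass
class OrdinationResult:
    sample_ids: list[str]
    feature_ids: list[str]
    scores: np.ndarray  # samples x components
    loadings: np.ndarray  # features x components
    explained_fraction: np.ndarray  # per-component fraction of total variance

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.n_components)]
        return pd.DataFrame(self.scores, index=pd.Index(self.sample_ids, name="sample_id"),
                            columns=cols)

    def loadings_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.n_components)]
        return pd.DataFrame(self.loadings, index=pd.Index(self.feature_ids, name="feature_id"),
                            columns=cols)


def pca(table: AbundanceTable, scale: str = "center") -> OrdinationResult:
    """Principal component analysis of samples over features.

    ``scale="center"`` subtracts feature means; ``"center_unit_variance"``
    additionally divides by the feature standard deviation, dropping
    constant features with a warning. Components are capped at
    min(n_samples - 1, n_features); ``scores @ loadings.T`` reconstructs the
    transformed matrix.
    """
    if scale not in ("center", "center_unit_variance"):
        raise UsageError(f"scale must be 'center' or 'center_unit_variance', got {scale!r}")
    x = table.values.T.astype(float)  # samples x features
    n_samples, n_features = x.shape
    if n_samples < 2:
        raise UsageError("PCA requires at least 2 samples")
    if n_features < 1:
        raise UsageError("PCA requires at least 1 feature")
    feature_ids = list(table.feature_ids)
    x = x - x.mean(axis=0)
    if scale == "center_unit_variance":
        sd = x.std(axis=0, ddof=1)
        constant = sd == 0
        if constant.any():
            dropped = [f for f, c in zip(feature_ids, constant) if c]
            warnings.warn(f"dropped constant features under unit-variance scaling: {dropped}",
                          stacklevel=2)
            x = x[:, ~constant]
            feature_ids = [f for f, c in zip(feature_ids, constant) if not c]
            if x.shape[1] == 0:
                raise UsageError("all features constant; nothing to decompose")
        x = x / x.std(axis=0, ddof=1)

    k = min(n_samples - 1, x.shape[1])
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    u, s, vt = u[:, :k], s[:k], vt[:k]
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(k):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]
    total = float((s**2).sum())
    explained = s**2 / total if total > 0 else np.zeros(k)
    return OrdinationResult(
        sample_ids=list(table.sample_ids),
        feature_ids=feature_ids,
        scores=u * s,
        loadings=vt.T,
        explained_fraction=explained,
    )


# ---------------------------------------------------------------------------
# hierarchical clustering


@dataclass
class ClusteringResult:
    """Row/column merge trees plus dendrogram leaf orders.

    Each tree is an (n-1) x 4 array of (cluster_a, cluster_b, height, size)
    with cluster_a < cluster_b; an axis that was not clustered is None.
    """

    row_tree: np.ndarray | None
    col_tree: np.ndarray | None
    row_order: list[int] | None
    col_order: list[int] | None
    distance_name: str
    linkage_name: str


def _distance_matrix(x: np.ndarray, distance: str, labels) -> np.ndarray:
    if distance == "euclidean":
        return squareform(pdist(x, metric="euclidean"))
    if distance == "correlation":
        sd = x.std(axis=1)
        if (sd == 0).any():
            bad = labels[int(np.where(sd == 0)[0][0])]
            raise ValidationError(
                f"row {bad!r} has zero variance; correlation distance undefined"
            )
        return squareform(pdist(x, metric="correlation"))  # 1 - Pearson r
    raise UsageError(f"distance must be 'euclidean' or 'correlation', got {distance!r}")


def linkage_matrix(dist: np.ndarray, linkage: str = "average") -> np.ndarray:
    """Agglomerate a square distance matrix into an (n-1) x 4 merge list.

    Lance-Williams updates for single (min), complete (max) and average
    (size-weighted mean) linkage. The pair merged at each step is the one
    with minimal distance; exact ties go to the lexicographically smallest
    pair of cluster ids, so the output is deterministic.
    """
    if linkage not in ("single", "complete", "average"):
        raise UsageError(f"linkage must be 'single', 'complete' or 'average', got {linkage!r}")
    n = dist.shape[0]
    if n < 2:
        raise UsageError("clustering requires at least 2 items")
    d = dist.astype(float).copy()
    np.fill_diagonal(d, np.inf)
    ids = list(range(n))  # cluster id at each active slot
    sizes = {i: 1 for i in range(n)}
    merges = np.empty((n - 1, 4))
    active = np.ones(n, dtype=bool)
    for step in range(n - 1):
        sub = np.where(active)[0]
        block = d[np.ix_(sub, sub)]
        iu = np.triu_indices(len(sub), k=1)
        vals = block[iu]
        best = vals.min()
        cand = np.where(vals == best)[0]
        bi, bj = min(
            tuple(sorted((ids[sub[iu[0][c]]], ids[sub[iu[1][c]]]))) for c in cand
        )
        sa = next(s for s in sub if ids[s] == bi)
        sb = next(s for s in sub if ids[s] == bj)
        na, nb = sizes[bi], sizes[bj]
        new_id = n + step
        merges[step] = (bi, bj, best, na + nb)
        # Lance-Williams update into slot sa
        for s in sub:
            if s in (sa, sb):
                continue
            if linkage == "single":
                d[sa, s] = d[s, sa] = min(d[sa, s], d[sb, s])
            elif linkage == "complete":
                d[sa, s] = d[s, sa] = max(d[sa, s], d[sb, s])
            else:
                d[sa, s] = d[s, sa] = (na * d[sa, s] + nb * d[sb, s]) / (na + nb)
        active[sb] = False
        ids[sa] = new_id
        sizes[new_id] = na + nb
    return merges


def leaf_order(tree: np.ndarray, n: int) -> list[int]:
    """Left-to-right dendrogram traversal, earlier-created subcluster first."""
    children = {n + i: (int(a), int(b)) for i, (a, b, _, _) in enumerate(tree)}

    def walk(c: int) -> list[int]:
        if c < n:
            return [c]
        a, b = children[c]
        return walk(a) + walk(b)

    return walk(n + len(tree) - 1)


def hierarchical_cluster(
    matrix,
    axis: str = "both",
    distance: str = "euclidean",
    linkage: str = "average",
) -> ClusteringResult:
    """Cluster the rows and/or columns of a matrix (DataFrame or ndarray)."""
    if axis not in ("rows", "cols", "both"):
        raise UsageError(f"axis must be 'rows', 'cols' or 'both', got {axis!r}")
    if isinstance(matrix, AbundanceTable):
        matrix = matrix.data
    df = pd.DataFrame(matrix)
    x = df.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValidationError("matrix contains missing or non-finite values")
    row_tree = col_tree = None
    row_ord = col_ord = None
    if axis in ("rows", "both"):
        row_tree = linkage_matrix(_distance_matrix(x, distance, df.index), linkage)
        row_ord = leaf_order(row_tree, x.shape[0])
    if axis in ("cols", "both"):
        col_tree = linkage_matrix(_distance_matrix(x.T, distance, df.columns), linkage)
        col_ord = leaf_order(col_tree, x.shape[1])
    return ClusteringResult(row_tree, col_tree, row_ord, col_ord, distance, linkage)
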