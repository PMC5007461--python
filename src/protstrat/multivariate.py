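"""Spearman-distance hierarchical clustering and PCA.

Distances are 1 - Spearman rank correlation (average ranks for ties),
computed between sample columns (or between protein rows). Agglomeration
uses scipy's standard linkage machinery (average linkage by default);
clusters come from cutting the dendrogram at the height yielding exactly k
clusters. PCA is a singular value decomposition of the protein-centred
matrix with a deterministic sign convention (largest-absolute loading
positive per component).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .containers import ProteinMatrix
from .errors import ConfigError, FormatError


@dataclass
class DistanceMatrix:
    ids: list[str]
    distances: np.ndarray  # symmetric, zero diagonal
    metric: str = "spearman"

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise FormatError("distance matrix shape does not match ids")
        if not np.allclose(d, d.T, atol=1e-12):
            raise FormatError("distance matrix is not symmetric")
        np.fill_diagonal(d, 0.0)
        self.distances = d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.distances, index=self.ids, columns=self.ids)


@dataclass
class Dendrogram:
    """Agglomerative merge tree over ``ids`` (scipy linkage encoding)."""

    ids: list[str]
    linkage: np.ndarray  # (n-1, 4) scipy linkage matrix
    method: str = "average"

    @property
    def merges(self) -> list[tuple[int, int, float]]:
        return [(int(a), int(b), float(h)) for a, b, h, _ in self.linkage]

    def leaf_order(self) -> list[str]:
        if len(self.ids) == 1:
            return list(self.ids)
        order = hierarchy.leaves_list(self.linkage)
        return [self.ids[i] for i in order]

    def to_newick(self) -> str:
        """Serialize the merge tree as a Newick string with branch heights."""
        if len(self.ids) == 1:
            return f"{self.ids[0]};"
        tree = hierarchy.to_tree(self.linkage)

        def render(node) -> str:
            if node.is_leaf():
                return self.ids[node.id]
            left, right = node.get_left(), node.get_right()
            lb = max(node.dist - left.dist, 0.0)
            rb = max(node.dist - right.dist, 0.0)
            return f"({render(left)}:{lb:g},{render(right)}:{rb:g})"

        return render(tree) + ";"


@dataclass
class PcaResult:
    scores: pd.DataFrame        # samples x components
    loadings: pd.DataFrame      # proteins x components, orthonormal columns
    explained_variance_ratio: np.ndarray


def spearman_distance(matrix: ProteinMatrix | pd.DataFrame,
                      axis: str = "columns") -> DistanceMatrix:
    """Pairwise 1 - Spearman rank correlation between samples (or proteins).

    Requires a complete (imputed) matrix. A constant column has undefined
    rank correlation and raises an error naming it.
    """
    values = matrix.values if isinstance(matrix, ProteinMatrix) else matrix
    if axis == "rows":
        values = values.T
    elif axis != "columns":
        raise ConfigError("axis must be 'columns' or 'rows'")
    if values.isna().any().any():
        raise ConfigError("spearman_distance requires a complete matrix; "
                          "impute missing values first")
    ids = [str(c) for c in values.columns]
    arr = values.to_numpy(dtype=float)
    constant = arr.std(axis=0) == 0
    if constant.any():
        bad = [ids[j] for j in np.flatnonzero(constant)]
        raise ConfigError(f"constant columns have undefined rank correlation: {bad}")
    if len(ids) == 1:
        rho = np.ones((1, 1))
    elif len(ids) == 2:
        r = float(stats.spearmanr(arr[:, 0], arr[:, 1]).statistic)
        rho = np.array([[1.0, r], [r, 1.0]])
    else:
        rho = np.asarray(stats.spearmanr(arr).statistic)
    return DistanceMatrix(ids=ids, distances=1.0 - rho, metric="spearman")


def hierarchical_cluster(dist: DistanceMatrix, linkage: str = "average"
                         ) -> Dendrogram:
    """Agglomerative clustering of a distance matrix.

    Linkage is one of {average, complete, single, ward}; scipy's merge
    ordering is deterministic for a fixed input.
    """
    if linkage not in ("average", "complete", "single", "ward"):
        raise ConfigError(f"unsupported linkage {linkage!r}")
    n = len(dist.ids)
    if n == 1:
        return Dendrogram(ids=list(dist.ids), linkage=np.empty((0, 4)),
                          method=linkage)
    condensed = squareform(dist.distances, checks=False)
    z = hierarchy.linkage(condensed, method=linkage)
    return Dendrogram(ids=list(dist.ids), linkage=z, method=linkage)


def cut_clusters(dend: Dendrogram, k: int) -> pd.Series:
    """Cluster labels (1..k) from cutting the dendrogram into k clusters."""
    if k < 1:
        raise ConfigError("k must be >= 1")
    n = len(dend.ids)
    if k > n:
        raise ConfigError(f"k={k} exceeds number of leaves {n}")
    if n == 1 or k == n:
        labels = np.arange(1, n + 1) if k == n else np.ones(n, dtype=int)
    else:
        labels = hierarchy.fcluster(dend.linkage, t=k, criterion="maxclust")
    return pd.Series(labels, index=dend.ids, name="cluster")


def pca(matrix: ProteinMatrix | pd.DataFrame,
        n_components: int | None = None) -> PcaResult:
    """PCA of samples via SVD of the protein-centred complete matrix.

    Rows (proteins) are centred across samples; components are directions in
    protein space, scores place samples on them. Explained-variance fractions
    are eigenvalues of the sample covariance over the total variance.
    """
    values = matrix.values if isinstance(matrix, ProteinMatrix) else matrix
    if values.shape[1] < 2:
        raise ConfigError("PCA requires at least 2 samples")
    if values.isna().any().any():
        raise ConfigError("PCA requires a complete matrix; impute first")

    x = values.to_numpy(dtype=float).T  # samples x proteins
    x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    total = (s ** 2).sum()
    explained = (s ** 2) / total if total > 0 else np.zeros_like(s)

    max_k = len(s)
    k = max_k if n_components is None else min(n_components, max_k)
    u, s, vt, explained = u[:, :k], s[:k], vt[:k], explained[:k]

    # sign convention: largest-absolute loading positive per component
    for comp in range(k):
        pivot = np.argmax(np.abs(vt[comp]))
        if vt[comp, pivot] < 0:
            vt[comp] *= -1.0
            u[:, comp] *= -1.0

    comp_names = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(u * s, index=values.columns, columns=comp_names)
    loadings = pd.DataFrame(vt.T, index=values.index, columns=comp_names)
    return PcaResult(scores=scores, loadings=loadings,
                     explained_variance_ratio=explained)
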