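"""Two-dimensional hierarchical clustering, PCA and spatial mapping.

Cells and genes are clustered with cosine distance and average linkage; the
cluster count is either fixed or selected by mean silhouette width. Gene-level
structure is summarized by the gene-gene Pearson correlation matrix, a PCA
biplot (scores and loadings on the first two components), and Gaussian kernel
density estimates of per-gene expression. Cluster labels are joined back to
cell centroids to map subpopulations into the tissue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import gaussian_kde
from sklearn.metrics import silhouette_score


@dataclass
class ClusterResult:
    axis: str  # "cells" or "genes"
    linkage_matrix: np.ndarray  # scipy (n-1, 4) merge table
    k: int
    assignment: pd.Series  # item -> cluster id (1..k)
    metric: str = "cosine"
    linkage_method: str = "average"
    silhouette_by_k: dict[int, float] | None = None

    def cut(self, k: int) -> pd.Series:
        """Re-cut the stored tree at a different k."""
        labels = fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.assignment.index, name="cluster")


def cosine_distance_matrix(X: pd.DataFrame | np.ndarray, axis: str = "cells") -> np.ndarray:
    """Pairwise cosine distances 1 − x·y/(‖x‖‖y‖) between rows (cells) or columns (genes)."""
    M = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    if axis == "genes":
        M = M.T
    elif axis != "cells":
        raise ValueError("axis must be 'cells' or 'genes'")
    norms = np.linalg.norm(M, axis=1)
    zero = np.flatnonzero(norms == 0)
    if len(zero):
        names = (
            list(np.asarray(X.columns if axis == "genes" else X.index)[zero])
            if isinstance(X, pd.DataFrame)
            else zero.tolist()
        )
        raise ValueError(f"zero-norm vectors on axis {axis!r}: {names[:10]}")
    sim = (M @ M.T) / np.outer(norms, norms)
    D = 1.0 - np.clip(sim, -1.0, 1.0)
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


def hierarchical_cluster(
    D: np.ndarray,
    k: int,
    items: pd.Index | list | None = None,
    axis: str = "cells",
    method: str = "average",
) -> ClusterResult:
    """Agglomerative clustering of a precomputed distance matrix, cut at ``k``."""
    n = D.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k={k} out of range for {n} items")
    Z = linkage(squareform(D, checks=False), method=method)
    labels = fcluster(Z, t=k, criterion="maxclust")
    index = pd.Index(items) if items is not None else pd.RangeIndex(n)
    return ClusterResult(
        axis=axis,
        linkage_matrix=Z,
        k=int(labels.max()),
        assignment=pd.Series(labels, index=index, name="cluster"),
        linkage_method=method,
    )


def select_k_silhouette(
    D: np.ndarray, k_range: range | list[int] = range(2, 11), method: str = "average"
) -> tuple[int, dict[int, float]]:
    """Pick k maximizing mean silhouette width on the distance matrix.

    Ties break toward the smallest k. Returns ``(k, {k: silhouette})``.
    """
    n = D.shape[0]
    Z = linkage(squareform(D, checks=False), method=method)
    scores: dict[int, float] = {}
    for k in k_range:
        if not (2 <= k <= n - 1):
            continue
        labels = fcluster(Z, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        scores[k] = float(silhouette_score(D, labels, metric="precomputed"))
    if not scores:
        raise ValueError("no valid k in range")
    best = max(sorted(scores), key=lambda k: scores[k])
    return best, scores


def cluster_cells(
    zscore: pd.DataFrame, k: int | None = None, k_range: range = range(2, 11)
) -> ClusterResult:
    """Cosine/average-linkage clustering of cells on the z-score layer."""
    D = cosine_distance_matrix(zscore, axis="cells")
    sil = None
    if k is None:
        k, sil = select_k_silhouette(D, k_range)
    result = hierarchical_cluster(D, k, items=zscore.index, axis="cells")
    result.silhouette_by_k = sil
    return result


def cluster_genes(
    zscore: pd.DataFrame, k: int | None = None, k_range: range = range(2, 11)
) -> ClusterResult:
    """Cosine/average-linkage clustering of genes (columns of the z-score layer)."""
    D = cosine_distance_matrix(zscore, axis="genes")
    sil = None
    if k is None:
        k, sil = select_k_silhouette(D, k_range)
    result = hierarchical_cluster(D, k, items=zscore.columns, axis="genes")
    result.silhouette_by_k = sil
    return result


def recluster_on_gene_subset(
    zscore: pd.DataFrame, gene_subset: list[str], k: int | None = None
) -> ClusterResult:
    """Recluster cells using only the listed genes (same metric and linkage)."""
    if not gene_subset:
        raise ValueError("gene_subset is empty")
    unknown = [g for g in gene_subset if g not in zscore.columns]
    if unknown:
        raise KeyError(f"genes not in matrix: {unknown}")
    sub = zscore[gene_subset]
    norms = np.linalg.norm(sub.to_numpy(dtype=float), axis=1)
    sub = sub.loc[norms > 0]  # cells silent on the subset carry no direction
    return cluster_cells(sub, k=k)


def gene_correlation_matrix(X: pd.DataFrame) -> pd.DataFrame:
    """Genes × genes Pearson correlation across cells.

    Zero-variance genes get correlation 0 (diagnostic emitted), 1 on the
    diagonal.
    """
    if len(X) < 3:
        raise ValueError("need at least 3 cells for a correlation matrix")
    sd = X.std(axis=0, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"zero-variance genes in correlation matrix: {list(X.columns[degenerate])}",
            stacklevel=2,
        )
    corr = X.corr(method="pearson")
    corr = corr.fillna(0.0)
    np.fill_diagonal(corr.values, 1.0)
    return corr


@dataclass
class PCAResult:
    scores: pd.DataFrame  # cells × components
    loadings: pd.DataFrame  # genes × components, orthonormal columns
    variance_explained: np.ndarray  # fractions, non-increasing, sums to 1
    mean: np.ndarray
    biplot_scores: pd.DataFrame  # scores / max |score|
    biplot_loadings: pd.DataFrame  # loadings / max loading norm


def pca_biplot(X: pd.DataFrame) -> PCAResult:
    """Exact PCA of the (pooled z-score) matrix via covariance eigendecomposition.

    Biplot scaling: scores divided by the maximum absolute score, loading
    vectors by the maximum loading norm — both axes then live in [−1, 1].
    """
    if len(X) <= 1:
        raise ValueError("PCA needs at least 2 observations")
    M = X.to_numpy(dtype=float)
    mean = M.mean(axis=0)
    C = np.cov(M - mean, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(C)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # sign convention: largest-|coefficient| entry of each loading is positive
    flips = np.sign(eigvecs[np.argmax(np.abs(eigvecs), axis=0), np.arange(eigvecs.shape[1])])
    flips[flips == 0] = 1.0
    eigvecs = eigvecs * flips
    scores = (M - mean) @ eigvecs
    total = eigvals.sum()
    var_explained = eigvals / total if total > 0 else np.full_like(eigvals, 1.0 / len(eigvals))
    comp_names = [f"PC{i + 1}" for i in range(eigvecs.shape[1])]
    scores_df = pd.DataFrame(scores, index=X.index, columns=comp_names)
    loadings_df = pd.DataFrame(eigvecs, index=X.columns, columns=comp_names)
    max_score = np.abs(scores[:, :2]).max() if scores.size else 1.0
    max_norm = np.linalg.norm(eigvecs[:, :2], axis=1).max() if eigvecs.size else 1.0
    return PCAResult(
        scores=scores_df,
        loadings=loadings_df,
        variance_explained=var_explained,
        mean=mean,
        biplot_scores=scores_df / (max_score or 1.0),
        biplot_loadings=loadings_df / (max_norm or 1.0),
    )


def spatial_map(cluster_result: ClusterResult, cell_meta: pd.DataFrame) -> pd.DataFrame:
    """Join cluster assignments to cell centroids for mapping back into tissue.

    ``cell_meta`` must be indexed like the assignment and carry
    ``cz, cy, cx`` (and optionally ``sample_id``).
    """
    missing = cluster_result.assignment.index.difference(cell_meta.index)
    if len(missing):
        raise KeyError(f"cells missing from metadata: {list(missing[:10])}")
    cols = [c for c in ("sample_id", "cz", "cy", "cx") if c in cell_meta.columns]
    out = cell_meta.loc[cluster_result.assignment.index, cols].copy()
    out["cluster"] = cluster_result.assignment
    return out


def gene_density(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Gaussian KDE (normal-reference bandwidth) evaluated on ``grid``.

    The workhorse behind violin plots of per-gene expression. Degenerate
    (zero-variance) input raises, since a KDE bandwidth cannot be formed.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < 2:
        raise ValueError("need at least 2 finite values")
    if np.std(values) == 0:
        raise ValueError("zero-variance input: density is a spike at the single value")
    kde = gaussian_kde(values, bw_method="silverman")
    return kde(np.asarray(grid, dtype=float))
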