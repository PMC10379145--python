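"""Heatmap preparation, hierarchical clustering, PCA, and a quantitative
group-separation score.

The underlying question: does the expression of a chosen miRNA/mRNA panel
divide two phenotype groups (e.g. healthy controls vs diabetic kidney disease
with macroalbuminuria) into separate clusters? Rather than judging a
dendrogram by eye, clustering at k = 2 is scored against the true group
labels with cluster purity and the adjusted Rand index.

Defaults mirror the common heatmap workflow: row-wise z-scaling, Euclidean
distance, complete linkage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage as scipy_linkage
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

from .data_model import DataError, ParameterError

__all__ = [
    "ClusteringResult",
    "SeparationResult",
    "HeatmapData",
    "prepare_heatmap",
    "hierarchical_cluster",
    "pca_scores",
    "separation_score",
    "assess_separation",
]

METRICS = ("euclidean", "correlation", "cityblock", "cosine")
LINKAGES = ("complete", "average", "single", "ward")


@dataclass(frozen=True)
class ClusteringResult:
    """Agglomerative merge tree with deterministic cuts."""

    distance_metric: str
    linkage: str
    merges: np.ndarray  # scipy linkage matrix: (left, right, height, size)
    leaf_order: tuple[int, ...]
    item_ids: tuple[str, ...]

    def cut(self, k: int) -> pd.Series:
        """Cluster labels (1..k) at a k-cluster cut."""
        if k < 1 or k > len(self.item_ids):
            raise ParameterError(f"k must lie in [1, {len(self.item_ids)}]")
        labels = fcluster(self.merges, t=k, criterion="maxclust")
        return pd.Series(labels, index=list(self.item_ids), name="cluster")

    @property
    def merge_heights(self) -> np.ndarray:
        return self.merges[:, 2]


@dataclass(frozen=True)
class HeatmapData:
    matrix: pd.DataFrame  # scaled values, original index/columns
    row_order: tuple[str, ...]
    col_order: tuple[str, ...]
    constant_rows: tuple[str, ...]  # rows with zero variance, passed through as zeros


@dataclass(frozen=True)
class SeparationResult:
    purity: float
    adjusted_rand_index: float
    pca_coordinates: pd.DataFrame  # samples x components
    variance_explained: tuple[float, ...]
    cluster_labels: pd.Series


def prepare_heatmap(
    log2cpm: pd.DataFrame,
    features: Iterable[str],
    row_scaling: str = "zscore",
    metric: str = "euclidean",
    linkage: str = "complete",
) -> HeatmapData:
    """Row-scale a feature subset and order rows/columns by clustering.

    ``row_scaling="zscore"`` centers each row and divides by its sample
    standard deviation (n-1); constant rows cannot be scaled and pass through
    as zeros, flagged in ``constant_rows``.
    """
    feats = list(features)
    if not feats:
        raise ParameterError("empty feature set")
    missing = set(feats) - set(log2cpm.index)
    if missing:
        raise DataError(f"features absent from matrix: {sorted(missing)}")
    if row_scaling not in ("none", "zscore"):
        raise ParameterError(f"row_scaling must be 'none' or 'zscore', got {row_scaling!r}")
    sub = log2cpm.loc[feats].astype(float)
    constant: tuple[str, ...] = ()
    if row_scaling == "zscore":
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        flat = sd == 0
        constant = tuple(sub.index[flat])
        scaled = sub.sub(mean, axis=0)
        scaled = scaled.div(sd.where(~flat, 1.0), axis=0)
        scaled.loc[flat] = 0.0
        sub = scaled
    row_order = tuple(sub.index) if sub.shape[0] < 2 else tuple(
        sub.index[list(hierarchical_cluster(sub.to_numpy(), metric, linkage, list(sub.index)).leaf_order)]
    )
    col_order = tuple(sub.columns) if sub.shape[1] < 2 else tuple(
        sub.columns[list(hierarchical_cluster(sub.to_numpy().T, metric, linkage, list(sub.columns)).leaf_order)]
    )
    return HeatmapData(matrix=sub, row_order=row_order, col_order=col_order, constant_rows=constant)


def hierarchical_cluster(
    matrix: np.ndarray | pd.DataFrame,
    metric: str = "euclidean",
    linkage: str = "complete",
    item_ids: Sequence[str] | None = None,
) -> ClusteringResult:
    """Agglomerative clustering of rows; deterministic given input order."""
    if isinstance(matrix, pd.DataFrame):
        if item_ids is None:
            item_ids = list(matrix.index)
        matrix = matrix.to_numpy()
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise DataError("need a 2-D matrix with at least 2 rows to cluster")
    if np.isnan(matrix).any():
        raise DataError("matrix contains NaN")
    if metric not in METRICS:
        raise ParameterError(f"metric must be one of {METRICS}")
    if linkage not in LINKAGES:
        raise ParameterError(f"linkage must be one of {LINKAGES}")
    merges = scipy_linkage(matrix, method=linkage, metric=metric)
    ids = tuple(item_ids) if item_ids is not None else tuple(str(i) for i in range(matrix.shape[0]))
    return ClusteringResult(
        distance_metric=metric,
        linkage=linkage,
        merges=merges,
        leaf_order=tuple(int(i) for i in leaves_list(merges)),
        item_ids=ids,
    )


def pca_scores(
    matrix: np.ndarray | pd.DataFrame,
    center: bool = True,
    scale: bool = False,
    n_components: int | None = None,
) -> tuple[pd.DataFrame, tuple[float, ...]]:
    """PCA of samples-as-rows data via SVD.

    Returns sample coordinates on the leading principal components and the
    fraction of total variance each explains (non-increasing, summing to at
    most 1). ``scale`` standardizes columns by their sample SD before the
    decomposition; zero-variance columns are left unscaled.
    """
    ids = list(matrix.index) if isinstance(matrix, pd.DataFrame) else None
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise DataError("PCA needs at least 2 samples")
    n, p = X.shape
    max_k = min(n - 1, p)
    k = max_k if n_components is None else int(n_components)
    if not (1 <= k <= max_k):
        raise ParameterError(f"n_components must lie in [1, {max_k}]")
    if center:
        X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        X = X / np.where(sd == 0, 1.0, sd)
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    coords = X @ vt[:k].T
    total = float(np.sum(s**2))
    explained = tuple((s[:k] ** 2 / total).tolist()) if total > 0 else tuple([0.0] * k)
    frame = pd.DataFrame(
        coords,
        index=ids if ids is not None else range(n),
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return frame, explained


def separation_score(
    assignment: Sequence[int] | pd.Series, labels: Sequence[str] | pd.Series
) -> tuple[float, float]:
    """Cluster purity and adjusted Rand index against true group labels.

    Purity is the best achievable fraction of correctly assigned samples over
    one-to-one cluster-to-group mappings (Hungarian assignment on the
    contingency table); it is invariant to relabeling either side and never
    below the largest class frequency.
    """
    assign = np.asarray(pd.Series(assignment).to_numpy())
    labs = np.asarray(pd.Series(labels).to_numpy())
    if assign.shape[0] != labs.shape[0]:
        raise DataError("assignment and labels differ in length")
    contingency = pd.crosstab(pd.Series(assign), pd.Series(labs)).to_numpy()
    square = np.zeros((max(contingency.shape),) * 2)
    square[: contingency.shape[0], : contingency.shape[1]] = contingency
    rows, cols = linear_sum_assignment(square, maximize=True)
    purity = float(square[rows, cols].sum() / assign.shape[0])
    ari = float(adjusted_rand_score(labs, assign))
    return purity, ari


def assess_separation(
    log2cpm: pd.DataFrame,
    features: Iterable[str],
    labels: pd.Series,
    k: int = 2,
    metric: str = "euclidean",
    linkage: str = "complete",
    row_scaling: str = "zscore",
    n_components: int = 2,
) -> SeparationResult:
    """End-to-end group-separation assessment on a feature panel.

    Rows of ``log2cpm`` are features; ``labels`` maps each sample to its true
    group. Samples are clustered (on the row-scaled panel submatrix) and
    scored at a k-cluster cut, and projected onto principal components.
    """
    heat = prepare_heatmap(log2cpm, features, row_scaling=row_scaling, metric=metric, linkage=linkage)
    sample_matrix = heat.matrix.T  # samples x features
    clustering = hierarchical_cluster(sample_matrix, metric=metric, linkage=linkage)
    assignment = clustering.cut(k)
    labels = labels.loc[sample_matrix.index]
    purity, ari = separation_score(assignment, labels)
    n_comp = min(n_components, sample_matrix.shape[0] - 1, sample_matrix.shape[1])
    coords, explained = pca_scores(sample_matrix, n_components=n_comp)
    return SeparationResult(
        purity=purity,
        adjusted_rand_index=ari,
        pca_coordinates=coords,
        variance_explained=explained,
        cluster_labels=assignment,
    )
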