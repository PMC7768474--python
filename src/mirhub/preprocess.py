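"""Feature filtering, uncentered-correlation/centroid-linkage clustering and
the survival-guided C1 / non-C1 labeling.

The clustering reproduces the Cluster 3.0 (C Clustering Library) combination
of *uncentered correlation* distance -- ``1 - (x . y)/(|x||y|)`` without mean
centering -- with *centroid linkage*, where each cluster is represented by
the size-weighted mean of its member vectors in the original coordinate
space and merge heights are distances between those centroids.  This
combination is not available in scipy's linkage (which restricts centroid
linkage to Euclidean distance), so the agglomeration is implemented here.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from dataclasses import dataclass, field

from . import survival as surv
from .containers import ExpressionMatrix, SubtypeLabeling

logger = logging.getLogger(__name__)


def filter_detected(
    expr: ExpressionMatrix,
    labels: SubtypeLabeling | None = None,
    min_fraction: float = 0.5,
    is_c1: pd.Series | None = None,
) -> ExpressionMatrix:
    """Keep features with counts > 0 in >= ``min_fraction`` of either group.

    Detection is assessed separately in the C1 and the non-C1 group; a
    feature survives if it clears the fraction in *either* (OR semantics).
    """
    if expr.scale != "raw":
        raise ValueError("detection filter operates on raw counts")
    if is_c1 is None:
        if labels is None:
            raise ValueError("provide labels or is_c1")
        is_c1 = labels.is_c1
    is_c1 = is_c1.reindex(expr.sample_ids)
    if is_c1.isna().any():
        raise ValueError("labels do not cover all samples")
    c1_cols = [s for s, f in is_c1.items() if f]
    non_cols = [s for s, f in is_c1.items() if not f]
    if not c1_cols or not non_cols:
        raise ValueError("both C1 and non-C1 groups must be non-empty")
    detected = expr.values > 0
    frac_c1 = detected[c1_cols].mean(axis=1)
    frac_non = detected[non_cols].mean(axis=1)
    keep = (frac_c1 >= min_fraction) | (frac_non >= min_fraction)
    return ExpressionMatrix(expr.values.loc[keep], scale="raw")


def filter_top_variance(expr: ExpressionMatrix, quantile: float = 0.75) -> ExpressionMatrix:
    """Retain features whose SD reaches the given quantile of feature SDs.

    The quantile uses linear interpolation between order statistics, and all
    features tied at the threshold are kept.  If every SD is identical the
    matrix is returned unchanged with a warning.
    """
    if expr.n_features < 4:
        raise ValueError("variance filter needs at least 4 features")
    sds = expr.values.std(axis=1, ddof=1)
    if np.isclose(sds.max(), sds.min()):
        warnings.warn("all feature SDs equal; retaining all features", stacklevel=2)
        return expr
    threshold = float(np.quantile(sds, quantile, method="linear"))
    keep = sds >= threshold
    return ExpressionMatrix(expr.values.loc[keep], scale=expr.scale)


def uncentered_correlation_distance(x: np.ndarray, y: np.ndarray) -> float:
    """``1 - (x . y) / (|x| |y|)``, in [0, 2]; errors on zero-norm input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size == 0:
        raise ValueError("vectors must share a nonzero 1-D shape")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("uncentered correlation undefined for zero-norm vector")
    return float(1.0 - (x @ y) / (nx * ny))


def _pairwise_uncentered(M: np.ndarray) -> np.ndarray:
    """Pairwise uncentered correlation distances between rows of ``M``."""
    norms = np.linalg.norm(M, axis=1)
    if (norms == 0).any():
        raise ValueError("zero-norm vector among items")
    G = (M @ M.T) / np.outer(norms, norms)
    D = 1.0 - G
    np.fill_diagonal(D, 0.0)
    return D


@dataclass
class Dendrogram:
    """Merge list in scipy convention: leaf ids 0..n-1, internal n..2n-2."""

    merges: list[tuple[int, int, float]]
    leaf_ids: list[str]

    def __post_init__(self) -> None:
        if len(self.merges) != len(self.leaf_ids) - 1:
            raise ValueError("a dendrogram over n leaves requires n-1 merges")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)


def hierarchical_cluster(
    expr: ExpressionMatrix,
    center: str | None = "median",
) -> Dendrogram:
    """Agglomerate samples by uncentered correlation / centroid linkage.

    ``center="median"`` subtracts each feature's median before computing
    distances (the Cluster 3.0 habit for expression heatmaps); pass ``None``
    to cluster the raw log2 values.  Ties in the minimal distance are broken
    by the lowest (row, column) cluster-index pair, making the merge order
    deterministic.
    """
    if expr.n_samples < 2:
        raise ValueError("need at least 2 samples to cluster")
    M = expr.values.to_numpy(dtype=float).T  # samples x features
    if center == "median":
        M = M - np.median(M, axis=0, keepdims=True)
    elif center is not None:
        raise ValueError(f"unknown centering {center!r}")

    n = M.shape[0]
    cent = list(M.copy())  # per-cluster centroid vectors
    size = [1.0] * n
    ids = list(range(n))  # scipy-style cluster ids, parallel to cent/size
    D = _pairwise_uncentered(M)
    iu = np.tril_indices(n)
    D[iu] = np.inf  # keep only i<j entries; row-major argmin = lowest (i, j)

    merges: list[tuple[int, int, float]] = []
    next_id = n
    for _ in range(n - 1):
        flat = int(np.argmin(D))
        bi, bj = divmod(flat, D.shape[1])
        best = float(D[bi, bj])
        a_id, b_id = ids[bi], ids[bj]
        merges.append((min(a_id, b_id), max(a_id, b_id), best))

        new_size = size[bi] + size[bj]
        new_cent = (size[bi] * cent[bi] + size[bj] * cent[bj]) / new_size
        cent[bi], size[bi], ids[bi] = new_cent, new_size, next_id
        del cent[bj], size[bj], ids[bj]
        D = np.delete(np.delete(D, bj, axis=0), bj, axis=1)
        normi = np.linalg.norm(new_cent)
        if normi == 0:
            raise ValueError("zero-norm centroid encountered")
        for j in range(len(ids)):
            if j == bi:
                continue
            nj = np.linalg.norm(cent[j])
            d = 1.0 - (new_cent @ cent[j]) / (normi * nj)
            if j < bi:
                D[j, bi] = d
            else:
                D[bi, j] = d
        next_id += 1
    return Dendrogram(merges=merges, leaf_ids=expr.sample_ids)


def cut_k_branches(dendrogram: Dendrogram, k: int = 4) -> pd.Series:
    """Partition leaves into ``k`` clusters by removing the k-1 highest merges.

    Ties in merge height are resolved by removing the later merge first.
    Cluster labels are 1..k in order of each cluster's first leaf.
    """
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    order = sorted(
        range(n - 1),
        key=lambda m: (dendrogram.merges[m][2], m),
        reverse=True,
    )
    removed = set(order[: k - 1])
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for m, (a, b, _h) in enumerate(dendrogram.merges):
        node = n + m
        if m in removed:
            continue
        for child in (a, b):
            parent[find(child)] = find(node)
    roots = [find(i) for i in range(n)]
    label_of: dict[int, int] = {}
    labels = []
    for r in roots:
        if r not in label_of:
            label_of[r] = len(label_of) + 1
        labels.append(label_of[r])
    return pd.Series(labels, index=dendrogram.leaf_ids, name="cluster")


def assign_c1(
    clusters: pd.Series,
    clinical: pd.DataFrame,
    horizon: float = 3.0,
    pool_alpha: float = 0.05,
) -> SubtypeLabeling:
    """Name the worst-prognosis cluster C1 and pool the rest as non-C1.

    C1 is the cluster with the lowest Kaplan-Meier survival at ``horizon``
    years (tie-break: lowest restricted-mean survival, then lowest cluster
    label).  Pairwise log-rank p-values among the pooled clusters are
    recorded; pooling proceeds regardless, with a warning when any pair
    differs at ``pool_alpha``.
    """
    common = clusters.index.intersection(clinical.index)
    if len(common) == 0:
        raise ValueError("clusters and clinical table share no samples")
    clusters = clusters.loc[common]
    data = surv.truncate_followup(clinical.loc[common], horizon)

    stats = {}
    for cid, members in clusters.groupby(clusters).groups.items():
        sub = data.loc[members]
        if sub["event"].sum() == 0 and sub["time"].sum() == 0:
            raise ValueError(f"cluster {cid} has no events and no follow-up")
        stats[cid] = (surv.survival_at(sub, horizon), surv.restricted_mean(sub, horizon))

    ordered = sorted(stats, key=lambda c: (stats[c][0], stats[c][1], c))
    c1 = ordered[0]
    runner = ordered[1] if len(ordered) > 1 else None
    if runner is not None and np.isclose(stats[c1][0], stats[runner][0]) and np.isclose(
        stats[c1][1], stats[runner][1]
    ):
        warnings.warn(
            "tied survival between candidate C1 clusters; lowest cluster label chosen",
            stacklevel=2,
        )

    pooled = [c for c in stats if c != c1]
    pvals: dict[tuple[int, int], float] = {}
    for i, a in enumerate(pooled):
        for b in pooled[i + 1 :]:
            mask = clusters.isin([a, b])
            _chi2, p = surv.log_rank_test(data.loc[mask.index[mask]], clusters[mask])
            pvals[(a, b)] = p
            if p < pool_alpha:
                warnings.warn(
                    f"pooled clusters {a} and {b} differ in survival (log-rank p={p:.3g})",
                    stacklevel=2,
                )
    logger.info("C1 assigned to cluster %s; pooled %s", c1, pooled)
    return SubtypeLabeling(cluster_of=clusters, c1_cluster_id=c1, pooling_pvalues=pvals)
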