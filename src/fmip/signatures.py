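"""Dynamic-response fingerprints and their clustering.

Two complementary views of signaling dynamics: (i) hierarchical clustering
of condition-mean response fingerprints, which separates biosensors into
strong / middle / weak response classes, and (ii) K-means clustering of
pooled single-cell trajectories into a small set of representative temporal
patterns, with each condition summarised by the proportion of its cells in
each pattern — its dynamic signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.cluster import KMeans


@dataclass
class HierarchicalClustering:
    linkage: np.ndarray        # scipy condensed linkage matrix
    order: np.ndarray          # leaf order of the dendrogram
    labels: np.ndarray | None  # flat labels at the requested cut, 0-based


def hierarchical_cluster(
    matrix,
    metric: str = "euclidean",
    method: str = "ward",
    k: int | None = None,
    impute: bool = False,
) -> HierarchicalClustering:
    """Agglomerative clustering of fingerprint rows (default Euclidean/Ward).

    NaN cells raise unless ``impute`` replaces them with the column mean.
    With ``k`` the tree is cut into k flat clusters.
    """
    X = np.array(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 rows")
    if np.isnan(X).any():
        if not impute:
            raise ValueError("matrix contains NaN; set impute=True to "
                             "fill with column means")
        col_mean = np.nanmean(X, axis=0)
        X = np.where(np.isnan(X), col_mean, X)
    Z = hierarchy.linkage(X, method=method, metric=metric)
    order = np.asarray(hierarchy.dendrogram(Z, no_plot=True)["leaves"])
    labels = None
    if k is not None:
        labels = hierarchy.fcluster(Z, t=k, criterion="maxclust") - 1
    return HierarchicalClustering(Z, order, labels)


def resample_to_grid(
    times_list: list[np.ndarray],
    values_list: list[np.ndarray],
    n_points: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate trajectories onto a shared grid.

    The grid spans the common time window (latest start to earliest end);
    returns (grid, matrix of shape (n_cells, n_points)).
    """
    if not times_list:
        raise ValueError("no trajectories given")
    start = max(float(t[0]) for t in times_list)
    end = min(float(t[-1]) for t in times_list)
    if end <= start:
        raise ValueError("trajectories share no common time span")
    grid = np.linspace(start, end, n_points)
    mat = np.stack([np.interp(grid, np.asarray(t, float),
                              np.asarray(v, float))
                    for t, v in zip(times_list, values_list)])
    return grid, mat


def kmeans_patterns(
    trajectories,
    k: int = 6,
    seed: int = 0,
    n_restarts: int = 25,
) -> tuple[np.ndarray, np.ndarray]:
    """K-means clustering of pooled single-cell trajectories.

    Rows are cells on a common time grid.  Best of ``n_restarts``
    k-means++ initialisations under the squared-Euclidean objective;
    deterministic for a fixed seed.  Returns (centroids (k, T), labels).
    """
    X = np.asarray(trajectories, dtype=float)
    if X.ndim != 2:
        raise ValueError("trajectories must be a 2-D (cells x time) array")
    if not np.isfinite(X).all():
        raise ValueError("trajectories must be finite; interpolate first")
    if X.shape[0] < k:
        raise ValueError(f"need at least k={k} cells, got {X.shape[0]}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts,
                random_state=seed)
    labels = km.fit_predict(X)
    return km.cluster_centers_, labels


def cluster_proportions(
    labels,
    conditions,
    k: int | None = None,
) -> pd.DataFrame:
    """Per-condition fraction of cells in each trajectory cluster.

    Returns a (condition x k) table whose rows sum to 1 — the dynamic
    signature of each condition.
    """
    labels = np.asarray(labels)
    conditions = np.asarray(conditions)
    if labels.size != conditions.size:
        raise ValueError("labels and conditions must have equal length")
    if labels.size == 0:
        raise ValueError("no labeled cells")
    if k is None:
        k = int(labels.max()) + 1
    rows = {}
    for cond in pd.unique(conditions):
        sel = labels[conditions == cond]
        if sel.size == 0:
            raise ValueError(f"condition {cond!r} has no cells")
        rows[cond] = np.bincount(sel, minlength=k) / sel.size
    out = pd.DataFrame.from_dict(rows, orient="index",
                                 columns=[f"cluster_{i}" for i in range(k)])
    out.index.name = "condition_id"
    return out
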