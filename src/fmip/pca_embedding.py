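"""Condition-level PCA of signaling dynamics.

Conditions (cell lines, treatments, doses) are compared by stacking their
normalized mean-response traces into a (groups x time points) by biosensors
matrix, standardizing each biosensor column (center + unit variance, as R's
``prcomp(..., center=TRUE, scale.=TRUE)``) and taking the SVD.  Group
clouds in PC space are outlined by coverage ellipses that contain a stated
fraction of that group's time points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class Embedding:
    """PCA result: row scores, column loadings, explained variance."""

    scores: np.ndarray                  # (n, k)
    loadings: np.ndarray                # (p, k)
    explained_variance_ratio: np.ndarray
    column_means: np.ndarray
    column_scales: np.ndarray
    columns: list[str] | None = None


@dataclass
class CoverageEllipse:
    """Gaussian-fit ellipse scaled to an empirical coverage fraction."""

    center: np.ndarray
    axes: np.ndarray      # semi-axis lengths, descending
    angle_rad: float      # orientation of the major axis
    coverage: float       # achieved fraction of points inside


def build_condition_matrix(
    summaries: pd.DataFrame,
    groups: list[str] | None = None,
    biosensors: list[str] | None = None,
    value_col: str = "mean",
    group_col: str = "group_id",
) -> pd.DataFrame:
    """Stack group response traces into the PCA input matrix.

    ``summaries`` is long format with columns [group_col, biosensor_id,
    time_min, value_col].  Rows of the result are (group, time point)
    stacked group by group; columns are biosensors.  Every (group,
    biosensor) pair must be present on an identical time grid — e.g. 4
    groups x 85 time points x 14 biosensors gives a 340 x 14 matrix.
    """
    required = {group_col, "biosensor_id", "time_min", value_col}
    missing = required - set(summaries.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if groups is None:
        groups = list(pd.unique(summaries[group_col]))
    if biosensors is None:
        biosensors = list(pd.unique(summaries["biosensor_id"]))
    gaps = []
    blocks = []
    for g in groups:
        sub = summaries[summaries[group_col] == g]
        wide = sub.pivot_table(index="time_min", columns="biosensor_id",
                               values=value_col)
        for bs in biosensors:
            if bs not in wide.columns or wide[bs].isna().any():
                gaps.append((g, bs))
        if gaps:
            continue
        block = wide.loc[:, biosensors]
        block.index = pd.MultiIndex.from_product(
            [[g], block.index], names=[group_col, "time_min"])
        blocks.append(block)
    if gaps:
        raise ValueError(f"missing (group, biosensor) summaries: {gaps}")
    grids = {tuple(b.index.get_level_values("time_min")) for b in blocks}
    if len(grids) > 1:
        raise ValueError("groups are not on identical time grids")
    return pd.concat(blocks)


def pca(matrix) -> Embedding:
    """Centered, unit-variance PCA via SVD (prcomp-style).

    Columns are standardized with the sample (ddof=1) standard deviation;
    a zero-variance column is an error naming the offending biosensor.
    Signs are fixed so the largest-magnitude loading of each component is
    positive.  Explained-variance fractions sum to 1.
    """
    if isinstance(matrix, pd.DataFrame):
        columns = [str(c) for c in matrix.columns]
        X = matrix.to_numpy(dtype=float)
    else:
        columns = None
        X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need >= 2 rows")
    means = X.mean(axis=0)
    scales = X.std(axis=0, ddof=1)
    bad = np.flatnonzero(scales == 0)
    if bad.size:
        names = ([columns[i] for i in bad] if columns
                 else [f"column {i}" for i in bad])
        raise ValueError(f"zero-variance columns: {names}")
    Z = (X - means) / scales
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    # deterministic sign: largest |loading| of each PC is positive
    for j in range(Vt.shape[0]):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    scores = U * S
    evr = S ** 2 / np.sum(S ** 2)
    return Embedding(scores, Vt.T, evr, means, scales, columns)


def coverage_ellipse(points, fraction: float) -> CoverageEllipse:
    """Smallest Gaussian-shaped ellipse covering >= ``fraction`` of points.

    The ellipse shares the sample mean and covariance orientation; its
    Mahalanobis radius is the smallest empirical quantile whose coverage
    reaches the requested fraction, so the achieved coverage is an actual
    count of points, not a parametric approximation.
    """
    P = np.asarray(points, dtype=float)
    if P.ndim != 2 or P.shape[0] < 3 or P.shape[1] != 2:
        raise ValueError("need >= 3 two-dimensional points")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = P.shape[0]
    center = P.mean(axis=0)
    cov = np.cov(P, rowvar=False)
    try:
        cov_inv = np.linalg.inv(cov)
        if np.linalg.cond(cov) > 1e12:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn("degenerate covariance; falling back to an "
                      "axis-aligned bounding ellipse", stacklevel=2)
        half = np.maximum((P.max(axis=0) - P.min(axis=0)) / 2.0, 1e-12)
        return CoverageEllipse(center, np.sort(half)[::-1],
                               0.0 if half[0] >= half[1] else np.pi / 2, 1.0)
    diff = P - center
    d = np.sqrt(np.einsum("ij,jk,ik->i", diff, cov_inv, diff))
    d_sorted = np.sort(d)
    idx = int(np.ceil(fraction * n)) - 1
    radius = d_sorted[idx]
    coverage = float(np.sum(d <= radius) / n)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    axes = np.sqrt(np.maximum(eigval, 0.0)) * radius
    angle = float(np.arctan2(eigvec[1, 0], eigvec[0, 0]))
    return CoverageEllipse(center, axes, angle, coverage)
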