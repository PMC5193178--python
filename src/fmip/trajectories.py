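"""Single-cell trajectory normalization and condition-level summaries.

Two-stage normalization removes nuisance trends from FRET-ratio time
courses: division by each cell's own pre-stimulation mean (baseline
normalization, resting activity -> 1) and division by the per-time-point
mean of vehicle-treated cells (removes expression drift and photobleaching
shared with untreated cells).  Summaries report the condition mean +/- SEM
pooled over all cells of all replicate experiments, replicate
reproducibility as a coefficient of variation over time, and the
expression-response association as Kendall's tau.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats


def normalize_baseline(times, values, stimulation_time: float) -> np.ndarray:
    """Divide a trajectory by its pre-stimulation mean.

    Requires at least two samples before ``stimulation_time``; the output's
    pre-stimulus mean is exactly 1.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    pre = times < stimulation_time
    if pre.sum() < 2:
        raise ValueError("need >= 2 pre-stimulus samples for baseline "
                         "normalization")
    baseline = values[pre].mean()
    if baseline <= 0:
        raise ValueError("non-positive pre-stimulus baseline")
    return values / baseline


def normalize_vehicle(values, vehicle_mean) -> np.ndarray:
    """Divide each time point by the vehicle-condition mean at that time."""
    values = np.asarray(values, dtype=float)
    vehicle_mean = np.asarray(vehicle_mean, dtype=float)
    if values.shape[-1] != vehicle_mean.shape[-1]:
        raise ValueError("vehicle mean does not cover the trajectory grid")
    if np.any(~np.isfinite(vehicle_mean)) or np.any(vehicle_mean <= 0):
        raise ValueError("vehicle mean must be finite and > 0 at every "
                         "time point")
    return values / vehicle_mean


def normalize_max(trace) -> np.ndarray:
    """Scale a summary trace to a maximum of 1."""
    trace = np.asarray(trace, dtype=float)
    peak = np.nanmax(trace)
    if not peak > 0:
        raise ValueError("trace maximum must be > 0 for max-normalization")
    return trace / peak


def condition_mean_sem(traces) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and SEM over cells (rows) on a shared time grid.

    SEM = sd / sqrt(n) with the sample (ddof=1) standard deviation, pooling
    all cells from all replicates of the condition.  A single cell has
    SEM 0 by convention.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    n = traces.shape[0]
    mean = traces.mean(axis=0)
    if n < 2:
        return mean, np.zeros_like(mean)
    sem = traces.std(axis=0, ddof=1) / np.sqrt(n)
    return mean, sem


def replicate_cv(replicate_means) -> tuple[np.ndarray, float]:
    """Coefficient of variation (%) across replicate mean traces over time.

    At each time point CV = 100 * sd / mean over the replicate means
    (rows); the average CV is the mean over time points.  Time points with
    zero mean give NaN and are excluded from the average with a warning.
    """
    reps = np.atleast_2d(np.asarray(replicate_means, dtype=float))
    if reps.shape[0] < 2:
        raise ValueError("need >= 2 replicate traces")
    mean = reps.mean(axis=0)
    sd = reps.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0, 100.0 * sd / mean, np.nan)
    finite = np.isfinite(cv)
    if not finite.all():
        warnings.warn("replicate_cv: zero-mean time points excluded from "
                      "the average", stacklevel=2)
    if not finite.any():
        return cv, np.nan
    return cv, float(cv[finite].mean())


def expression_response_correlation(expression,
                                    response) -> tuple[float, float]:
    """Kendall tau-b between biosensor expression and maximal response.

    Expression is each cell's pre-stimulus mean CFP; response its maximal
    normalized ratio.  The p value is exact for fewer than 50 untied pairs
    and uses the normal approximation otherwise.
    """
    x = np.asarray(expression, dtype=float)
    y = np.asarray(response, dtype=float)
    if x.size != y.size:
        raise ValueError("expression and response must have equal length")
    if x.size < 3:
        raise ValueError("need >= 3 cells for the correlation")
    no_ties = (np.unique(x).size == x.size) and (np.unique(y).size == y.size)
    method = "exact" if (x.size < 50 and no_ties) else "asymptotic"
    res = stats.kendalltau(x, y, method=method)
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------------------------
# DataFrame-level pipeline
# --------------------------------------------------------------------------

#: columns required of a long-format trajectory table
TRAJECTORY_COLUMNS = ["cell_id", "biosensor_id", "condition_id",
                      "time_min", "ratio"]


def normalize_trajectories(
    df: pd.DataFrame,
    stimulation_time: float,
    vehicle_condition: str | None = None,
) -> pd.DataFrame:
    """Baseline- (and optionally vehicle-) normalize a long trajectory table.

    Adds a ``normalized`` column.  When ``vehicle_condition`` is given, the
    per-biosensor vehicle mean trace (itself baseline-normalized) divides
    every cell of that biosensor at each time point; vehicle cells are
    retained so downstream code can still see them.
    """
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    df = df.sort_values(["biosensor_id", "condition_id", "cell_id",
                         "time_min"]).reset_index(drop=True)

    def _per_cell(group: pd.DataFrame) -> np.ndarray:
        return normalize_baseline(group["time_min"].to_numpy(),
                                  group["ratio"].to_numpy(),
                                  stimulation_time)

    df["normalized"] = np.concatenate([
        _per_cell(g) for _, g in
        df.groupby(["biosensor_id", "condition_id", "cell_id"], sort=False)])

    if vehicle_condition is not None:
        out = []
        for bs, sub in df.groupby("biosensor_id", sort=False):
            veh = sub[sub["condition_id"] == vehicle_condition]
            if veh.empty:
                raise ValueError(f"no vehicle cells for biosensor {bs!r}")
            veh_mean = veh.groupby("time_min")["normalized"].mean()
            sub = sub.copy()
            mapped = sub["time_min"].map(veh_mean)
            if mapped.isna().any():
                raise ValueError(f"vehicle grid does not cover all time "
                                 f"points for biosensor {bs!r}")
            if (mapped <= 0).any():
                raise ValueError("vehicle mean must be > 0")
            sub["normalized"] = sub["normalized"] / mapped
            out.append(sub)
        df = pd.concat(out, ignore_index=True)
    return df


def summarize_conditions(df: pd.DataFrame,
                         value_col: str = "normalized") -> pd.DataFrame:
    """Condition summaries: mean, SEM and cell count per time point."""
    rows = []
    for (bs, cond), sub in df.groupby(["biosensor_id", "condition_id"]):
        wide = sub.pivot_table(index="cell_id", columns="time_min",
                               values=value_col)
        if wide.isna().any().any():
            raise ValueError(f"cells of ({bs}, {cond}) are not on a common "
                             f"time grid")
        mean, sem = condition_mean_sem(wide.to_numpy())
        for t, m, s in zip(wide.columns, mean, sem):
            rows.append({"biosensor_id": bs, "condition_id": cond,
                         "time_min": float(t), "mean": m, "sem": s,
                         "n_cells": wide.shape[0]})
    return pd.DataFrame(rows)
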