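"""Stimulus-interaction (synergy/antagonism) scoring.

For two stimuli A and B, each cell's response is reduced to the area under
its centered normalized trajectory (baseline- and untreated-normalized,
minus 1) over the post-stimulation span.  If A and B act independently the
mean AUC of the combined treatment should equal the sum of the single-
treatment mean AUCs; the synergy score

    Ss = mean(AUC_AB) - (mean(AUC_A) + mean(AUC_B))

is 0 under additivity, > 0 for synergism and < 0 for antagonism.  The
expectation's uncertainty is propagated as sqrt(SEM_A^2 + SEM_B^2), the
difference is tested with a Welch-type t statistic, p values are corrected
for multiple testing (Benjamini-Hochberg by default), and per biosensor the
scores are scaled to [-1, +1] by the largest magnitude observed, with
non-significant entries masked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .trajectories import normalize_baseline

_ADJUST_METHODS = {"fdr_bh": "fdr_bh", "holm": "holm",
                   "bonferroni": "bonferroni"}


def synergy_normalize(times, ratios, untreated_mean,
                      stimulation_time: float) -> np.ndarray:
    """Center a trajectory: ratio / baseline / untreated mean - 1.

    The result is ~0 before stimulation and equals the fractional activity
    change afterwards (exactly so for noiseless simulated cells).
    """
    times = np.asarray(times, dtype=float)
    untreated_mean = np.asarray(untreated_mean, dtype=float)
    if untreated_mean.shape[-1] != times.shape[-1]:
        raise ValueError("untreated mean does not cover the time grid")
    if np.any(untreated_mean <= 0):
        raise ValueError("untreated mean must be > 0")
    normalized = normalize_baseline(times, ratios, stimulation_time)
    return normalized / untreated_mean - 1.0


def auc(times, values, stimulation_time: float) -> float:
    """Signed trapezoidal area of a centered trace after stimulation.

    Negative excursions subtract; at least two post-stimulation samples are
    required.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    post = times >= stimulation_time
    if post.sum() < 2:
        raise ValueError("need >= 2 post-stimulation samples for the AUC")
    return float(np.trapezoid(values[post], times[post]))


def normality_check(aucs) -> tuple[float, float]:
    """Shapiro-Wilk normality statistic for a sample of per-cell AUCs.

    Reported for quality control (alongside a quantile-quantile look at
    the data); the pipeline does not branch on the outcome.
    """
    x = np.asarray(aucs, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def expected_additive(mean_a: float, sem_a: float, mean_b: float,
                      sem_b: float) -> tuple[float, float]:
    """Additive expectation of the combined response with propagated SEM.

    mean = mean_a + mean_b; sem = sqrt(sem_a^2 + sem_b^2) (independent
    errors, first-order variance propagation).
    """
    if sem_a < 0 or sem_b < 0:
        raise ValueError("SEMs must be >= 0")
    return mean_a + mean_b, float(np.hypot(sem_a, sem_b))


def synergy_test(
    observed_aucs,
    mean_expected: float,
    sem_expected: float,
    arm_stats: list[tuple[int, float]] | None = None,
) -> tuple[float, float, float]:
    """Test observed combined-treatment AUCs against the additive expectation.

    Returns (ss_raw, t, p) with ss_raw = mean(observed) - mean_expected and
    t = ss_raw / sqrt(SEM_obs^2 + SEM_exp^2).  Degrees of freedom follow
    Welch-Satterthwaite over the contributing samples: the observed arm and,
    when ``arm_stats`` supplies [(n_A, sem_A), (n_B, sem_B)], the two
    single-stimulus arms behind the expectation; otherwise df = n_obs - 1.
    """
    obs = np.asarray(observed_aucs, dtype=float)
    if obs.size < 2:
        raise ValueError("need >= 2 observed AUCs")
    n_obs = obs.size
    mean_obs = obs.mean()
    sem_obs = obs.std(ddof=1) / np.sqrt(n_obs)
    ss_raw = float(mean_obs - mean_expected)
    combined_var = sem_obs ** 2 + sem_expected ** 2
    if combined_var == 0:
        if ss_raw == 0:
            return 0.0, 0.0, 1.0
        warnings.warn("zero combined SE with nonzero difference; p = 0",
                      stacklevel=2)
        return ss_raw, np.inf * np.sign(ss_raw), 0.0
    t = ss_raw / np.sqrt(combined_var)
    terms = [(sem_obs ** 2, n_obs - 1)]
    if arm_stats:
        terms += [(sem ** 2, max(n - 1, 1)) for n, sem in arm_stats]
    denom = sum(v ** 2 / df for v, df in terms if v > 0)
    df = combined_var ** 2 / denom if denom > 0 else n_obs - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    return ss_raw, float(t), float(p)


def adjust_pvalues(pvalues, method: str = "fdr_bh") -> np.ndarray:
    """Multiple-testing correction (Benjamini-Hochberg step-up by default;
    also holm, bonferroni).  Adjusted values are monotone and <= 1."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    if method not in _ADJUST_METHODS:
        raise ValueError(f"unknown method {method!r}")
    if p.size == 0:
        return p
    return multipletests(p, method=_ADJUST_METHODS[method])[1]


def scale_and_mask(results: pd.DataFrame,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Scale raw scores to [-1, 1] per biosensor and mask insignificance.

    ss_scaled = ss_raw / max |ss_raw| within the biosensor (all-zero rows
    stay zero); entries with adjusted p >= alpha get ``masked`` = True.
    """
    required = {"biosensor_id", "ss_raw", "p_adj"}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = results.copy()
    scale = out.groupby("biosensor_id")["ss_raw"].transform(
        lambda s: s.abs().max())
    out["ss_scaled"] = np.where(scale > 0, out["ss_raw"] / scale, 0.0)
    out["masked"] = out["p_adj"] >= alpha
    return out


@dataclass
class SynergyMap:
    """Ward-clustered synergy matrix: orderings plus the mask layer."""

    matrix: pd.DataFrame          # reordered biosensors x condition pairs
    mask: pd.DataFrame            # True where insignificant
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None
    row_order: np.ndarray
    col_order: np.ndarray


def synergy_map(scores: pd.DataFrame,
                mask: pd.DataFrame | None = None) -> SynergyMap:
    """Hierarchically cluster the scaled-score matrix (Euclidean, Ward).

    ``scores`` is a complete biosensors x condition-pairs table of scaled
    scores; masked entries should already be imputed as 0 so they carry no
    distance.  Rows and columns are each clustered and reordered; a single
    row or column keeps the identity ordering.
    """
    X = scores.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("score matrix must be complete and finite")
    if mask is None:
        mask = pd.DataFrame(False, index=scores.index,
                            columns=scores.columns)

    def _order(data: np.ndarray):
        if data.shape[0] < 2:
            return None, np.arange(data.shape[0])
        Z = hierarchy.linkage(data, method="ward", metric="euclidean")
        return Z, np.asarray(hierarchy.dendrogram(Z, no_plot=True)["leaves"])

    row_Z, row_order = _order(X)
    col_Z, col_order = _order(X.T)
    reordered = scores.iloc[row_order, :].iloc[:, col_order]
    mask_r = mask.iloc[row_order, :].iloc[:, col_order]
    return SynergyMap(reordered, mask_r, row_Z, col_Z, row_order, col_order)


def synergy_analysis(
    auc_table: pd.DataFrame,
    pairs: dict[str, tuple[str, str, str]],
    alpha: float = 0.05,
    adjust: str = "fdr_bh",
) -> pd.DataFrame:
    """Run the full scoring pipeline over a per-cell AUC table.

    ``auc_table`` has columns [biosensor_id, condition_id, auc]; ``pairs``
    maps a pair id to (condition_A, condition_B, condition_combined).
    Returns one row per biosensor x pair with observed and expected means
    and SEMs, Shapiro-Wilk statistics, the raw score, t, p, adjusted p,
    scaled score and mask flag.
    """
    required = {"biosensor_id", "condition_id", "auc"}
    missing = required - set(auc_table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    rows = []
    for bs, sub in auc_table.groupby("biosensor_id"):
        by_cond = {c: g["auc"].to_numpy() for c, g in
                   sub.groupby("condition_id")}
        for pair_id, (cond_a, cond_b, cond_ab) in pairs.items():
            try:
                a, b, ab = by_cond[cond_a], by_cond[cond_b], by_cond[cond_ab]
            except KeyError as exc:
                raise ValueError(f"biosensor {bs!r} lacks AUCs for "
                                 f"condition {exc.args[0]!r}") from exc
            sem = lambda x: (x.std(ddof=1) / np.sqrt(x.size)
                             if x.size > 1 else 0.0)
            mean_exp, sem_exp = expected_additive(a.mean(), sem(a),
                                                  b.mean(), sem(b))
            w, w_p = (normality_check(ab) if 3 <= ab.size <= 5000
                      else (np.nan, np.nan))
            ss_raw, t, p = synergy_test(
                ab, mean_exp, sem_exp,
                arm_stats=[(a.size, sem(a)), (b.size, sem(b))])
            rows.append({
                "biosensor_id": bs, "pair_id": pair_id,
                "mean_observed": ab.mean(), "sem_observed": sem(ab),
                "mean_expected": mean_exp, "sem_expected": sem_exp,
                "shapiro_w": w, "shapiro_p": w_p,
                "ss_raw": ss_raw, "t_stat": t, "p": p,
                "n_observed": ab.size,
            })
    results = pd.DataFrame(rows)
    results["p_adj"] = adjust_pvalues(results["p"].to_numpy(), method=adjust)
    return scale_and_mask(results, alpha=alpha)
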