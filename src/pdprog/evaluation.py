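"""Model-performance metrics and group comparisons.

Classification metrics (F1, ROC AUC, PR AUC, confusion matrix and derived
rates) with subject-level bootstrap uncertainty, Wilcoxon rank-sum
progressor-vs-non-progressor baseline comparisons, and polygenic-score
distribution contrasts by progression target.

Conventions: the classification threshold is 0.5; PR AUC uses the step-wise
(average-precision) convention rather than linear interpolation between PR
points, which can be optimistic; ROC AUC is the Mann-Whitney statistic
normalization.  Rank-sum tests use exact enumeration for small tie-free
groups (both n <= 20) and the continuity-corrected normal approximation
otherwise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.metrics import average_precision_score, roc_auc_score

log = logging.getLogger(__name__)

__all__ = [
    "ClassificationReport", "classification_metrics", "bootstrap_ci",
    "group_compare", "prs_distribution_report", "wilcoxon_ranksum",
]


@dataclass
class ClassificationReport:
    n: int
    tp: int
    fp: int
    fn: int
    tn: int
    f1: float
    roc_auc: float | None
    pr_auc: float | None
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    threshold: float = 0.5

    def to_dict(self) -> dict:
        return {k: (None if v is None else (float(v) if not isinstance(v, int)
                                            else v))
                for k, v in self.__dict__.items()}


def classification_metrics(y_true, y_prob, threshold: float = 0.5
                           ) -> ClassificationReport:
    """F1 / ROC AUC / PR AUC / confusion matrix at a fixed threshold.

    ROC AUC and PR AUC are undefined (reported as None, with a warning) when
    y_true contains a single class.
    """
    y_true = np.asarray(y_true).astype(int)
    y_prob = np.asarray(y_prob, dtype=float)
    if y_true.shape != y_prob.shape:
        raise ValueError("y_true and y_prob must have equal length")
    if y_prob.size and (y_prob.min() < 0 or y_prob.max() > 1):
        raise ValueError("y_prob outside [0, 1]")
    pred = (y_prob >= threshold).astype(int)
    tp = int(((pred == 1) & (y_true == 1)).sum())
    fp = int(((pred == 1) & (y_true == 0)).sum())
    fn = int(((pred == 0) & (y_true == 1)).sum())
    tn = int(((pred == 0) & (y_true == 0)).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    if len(np.unique(y_true)) < 2:
        warnings.warn("single-class y_true: ROC/PR AUC undefined")
        roc = pr = None
    else:
        roc = float(roc_auc_score(y_true, y_prob))
        pr = float(average_precision_score(y_true, y_prob))
    return ClassificationReport(
        n=int(y_true.size), tp=tp, fp=fp, fn=fn, tn=tn, f1=float(f1),
        roc_auc=roc, pr_auc=pr,
        sensitivity=recall,
        specificity=tn / (tn + fp) if tn + fp else 0.0,
        ppv=precision,
        npv=tn / (tn + fn) if tn + fn else 0.0,
        threshold=threshold)


def bootstrap_ci(metric_fn, y_true, y_prob, B: int = 1000,
                 level: float = 0.95, seed: int = 0) -> float:
    """Subject-level nonparametric bootstrap percentile-interval half-width.

    Resamples with degenerate metric values (e.g. single-class resamples for
    AUC) are skipped and logged.  Deterministic given seed.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    y_true = np.asarray(y_true).astype(int)
    y_prob = np.asarray(y_prob, dtype=float)
    rng = np.random.default_rng(seed)
    n = y_true.size
    vals = []
    skipped = 0
    for _ in range(B):
        idx = rng.integers(0, n, n)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                v = metric_fn(y_true[idx], y_prob[idx])
        except ValueError:
            v = None
        if v is None or not np.isfinite(v):
            skipped += 1
            continue
        vals.append(float(v))
    if skipped:
        log.info("bootstrap: skipped %d degenerate resamples", skipped)
    if not vals:
        raise ValueError("all bootstrap resamples degenerate")
    lo, hi = np.percentile(vals, [50 * (1 - level), 50 * (1 + level)])
    return float((hi - lo) / 2.0)


def wilcoxon_ranksum(a, b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when both groups have n <= 20 and there are no ties;
    normal approximation with continuity correction otherwise.  All-tied
    data returns p = 1 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size <= 1:
        warnings.warn("all values tied; rank-sum p = 1")
        return 1.0
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (len(a) <= 20 and len(b) <= 20 and not ties) \
        else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method,
                       use_continuity=True)
    return float(res.pvalue)


def group_compare(features: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Per-feature two-group comparison table: mean +- SE per group and the
    two-sided rank-sum p-value (progressors vs non-progressors layout)."""
    groups = groups.reindex(features.index)
    g1 = groups == 1
    rows = []
    for col in features.columns:
        x = features[col].astype(float)
        a, b = x[g1].dropna(), x[~g1].dropna()
        if a.empty or b.empty:
            continue
        rows.append({
            "feature": col,
            "mean_progressor": a.mean(),
            "se_progressor": a.std(ddof=1) / np.sqrt(len(a)) if len(a) > 1 else 0.0,
            "mean_nonprogressor": b.mean(),
            "se_nonprogressor": b.std(ddof=1) / np.sqrt(len(b)) if len(b) > 1 else 0.0,
            "p_value": wilcoxon_ranksum(a.values, b.values),
        })
    return pd.DataFrame(rows)


def prs_distribution_report(prs: pd.DataFrame, labels: pd.DataFrame
                            ) -> pd.DataFrame:
    """Polygenic-score distribution shifts by progression target.

    For every (score column) x (part, horizon) combination: group medians,
    direction of the non-progressor shift, and the rank-sum p-value.
    Subjects missing either the score or the label are dropped (count
    logged); a single-class target raises.
    """
    rows = []
    for (part, horizon), sub in labels.groupby(["part", "horizon"]):
        lab = sub.set_index("participant_id")["progressor"]
        joined = prs.join(lab, how="inner").dropna()
        n_drop = len(prs) - len(joined)
        if n_drop:
            log.info("target (%s,%s): dropped %d unjoined subjects",
                     part, horizon, n_drop)
        y = joined["progressor"].astype(int)
        if y.nunique() < 2:
            raise ValueError(f"target ({part},{horizon}) has a single class")
        for score in prs.columns:
            prog = joined.loc[y == 1, score].values
            nonprog = joined.loc[y == 0, score].values
            med_p, med_n = float(np.median(prog)), float(np.median(nonprog))
            rows.append({
                "score": score, "part": part, "horizon": horizon,
                "median_progressor": med_p,
                "median_nonprogressor": med_n,
                "nonprogressor_shift": ("right" if med_n > med_p
                                        else "left" if med_n < med_p
                                        else "none"),
                "p_value": wilcoxon_ranksum(prog, nonprog),
            })
    return pd.DataFrame(rows)
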