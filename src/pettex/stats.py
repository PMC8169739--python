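"""Group comparison and diagnostic-accuracy statistics.

Wilcoxon rank-sum (Mann-Whitney) tests compare each parameter between the
positive (tumor) and negative (pneumonitis) groups; empirical ROC curves
with trapezoid AUC, automatic orientation, upper-left-corner optimal
cutoffs and the DeLong test for correlated AUCs quantify diagnostic
accuracy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from sklearn import metrics as sk_metrics

__all__ = [
    "RocResult",
    "CutoffMetrics",
    "DelongResult",
    "wilcoxon_rank_sum",
    "roc_curve",
    "optimal_cutoff",
    "compare_auc",
    "group_comparison_report",
    "roc_report",
]

logger = logging.getLogger(__name__)


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns the Mann-Whitney U statistic of ``x`` and the two-sided p-value
    from the normal approximation with tie and continuity corrections —
    standard statistical-package behavior at cohort sizes around n = 30.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    res = sp_stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


@dataclass
class RocResult:
    """Empirical ROC curve of one parameter.

    ``orientation`` records whether higher or lower raw values indicate the
    positive class; it is chosen automatically so that the reported AUC is
    >= 0.5.  ``thresholds``, ``sensitivity`` and ``specificity`` are the
    operating points over all distinct score values (thresholds on the
    *oriented* score scale, rule: oriented score >= threshold is positive).
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    orientation: str  # "higher-is-positive" | "lower-is-positive"
    scores: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)

    @property
    def oriented_scores(self) -> np.ndarray:
        return self.scores if self.orientation == "higher-is-positive" else -self.scores


@dataclass(frozen=True)
class CutoffMetrics:
    """Diagnostic metrics at the upper-left-corner optimal operating point."""

    cutoff: float  # on the raw score scale
    rule: str  # ">=" (higher-is-positive) or "<=" (lower-is-positive)
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float


@dataclass(frozen=True)
class DelongResult:
    auc_a: float
    auc_b: float
    z: float
    p_value: float


def roc_curve(scores, labels) -> RocResult:
    """Empirical ROC with trapezoid AUC and automatic orientation."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("ROC needs both classes present")
    auc_raw = sk_metrics.roc_auc_score(labels, scores)
    if auc_raw >= 0.5:
        orientation, oriented = "higher-is-positive", scores
    else:
        orientation, oriented = "lower-is-positive", -scores
    fpr, tpr, thr = sk_metrics.roc_curve(labels, oriented, drop_intermediate=False)
    auc = float(sk_metrics.auc(fpr, tpr))
    return RocResult(
        thresholds=thr,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=auc,
        orientation=orientation,
        scores=scores,
        labels=labels,
    )


def optimal_cutoff(roc: RocResult) -> CutoffMetrics:
    """Operating point nearest the upper-left ROC corner.

    Minimizes ``sqrt((1 - sens)^2 + (1 - spec)^2)``; ties broken toward
    higher sensitivity, then higher (oriented) cutoff.  The confusion-matrix
    metrics are recomputed from the raw scores at the chosen cutoff.
    """
    finite = np.isfinite(roc.thresholds)
    thr = roc.thresholds[finite]
    sens = roc.sensitivity[finite]
    spec = roc.specificity[finite]
    dist = np.hypot(1.0 - sens, 1.0 - spec)
    # lexicographic selection: min distance, then max sensitivity, then max cutoff
    order = np.lexsort((-thr, -sens, dist))
    best = order[0]
    t = thr[best]

    oriented = roc.oriented_scores
    pred = oriented >= t
    pos = roc.labels
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    tn = int(np.sum(~pred & ~pos))
    fn = int(np.sum(~pred & pos))
    higher = roc.orientation == "higher-is-positive"
    return CutoffMetrics(
        cutoff=float(t if higher else -t),
        rule=">=" if higher else "<=",
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        ppv=tp / (tp + fp) if tp + fp else float("nan"),
        npv=tn / (tn + fn) if tn + fn else float("nan"),
        accuracy=(tp + tn) / (tp + fp + tn + fn),
    )


# -- DeLong test -------------------------------------------------------------


def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    t = np.zeros(n)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        t[i:j] = 0.5 * (i + j - 1) + 1
        i = j
    out = np.empty(n)
    out[order] = t
    return out


def _delong_auc_components(scores: np.ndarray, labels: np.ndarray):
    """AUC plus the DeLong structural components V10 (positives), V01."""
    pos = scores[labels]
    neg = scores[~labels]
    m, n = len(pos), len(neg)
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r = _midrank(pos)
    neg_r = _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    return auc, v10, v01


def compare_auc(roc_a: RocResult, roc_b: RocResult, paired: bool = True) -> DelongResult:
    """DeLong test for the difference between two AUCs.

    With ``paired=True`` (two parameters scored on the same lesions, the
    usual case) the covariance of the structural components is used; with
    ``paired=False`` the two cohorts are assumed independent.  Oriented
    scores are used so both AUCs are >= 0.5.  A zero-variance difference
    (e.g. identical score orderings) yields p = 1.
    """
    la, lb = roc_a.labels, roc_b.labels
    if paired and (len(la) != len(lb) or np.any(la != lb)):
        raise ValueError("paired comparison requires identical lesion labels")
    auc_a, v10_a, v01_a = _delong_auc_components(roc_a.oriented_scores, la)
    auc_b, v10_b, v01_b = _delong_auc_components(roc_b.oriented_scores, lb)

    def _var(v10, v01):
        s10 = v10.var(ddof=1) if len(v10) > 1 else 0.0
        s01 = v01.var(ddof=1) if len(v01) > 1 else 0.0
        return s10 / len(v10) + s01 / len(v01)

    if paired:
        s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1) / len(v10_a)
        s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1) / len(v01_a)
        s = s10 + s01
        var_diff = s[0, 0] + s[1, 1] - 2 * s[0, 1]
    else:
        var_diff = _var(v10_a, v01_a) + _var(v10_b, v01_b)

    diff = auc_a - auc_b
    if var_diff <= 0:
        z = 0.0
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / np.sqrt(var_diff)
        p = 2.0 * sp_stats.norm.sf(abs(z))
    return DelongResult(auc_a=float(auc_a), auc_b=float(auc_b), z=float(z),
                        p_value=float(min(p, 1.0)))


# -- cohort-level reports ----------------------------------------------------


def _split_groups(table: pd.DataFrame, label_col: str, positive_label):
    if label_col not in table.columns:
        raise ValueError(f"feature table has no label column {label_col!r}")
    is_pos = table[label_col] == positive_label
    if is_pos.all() or not is_pos.any():
        raise ValueError("both groups must be present in the cohort table")
    params = [
        c
        for c in table.columns
        if c != label_col and pd.api.types.is_numeric_dtype(table[c])
    ]
    return is_pos.to_numpy(), params


def group_comparison_report(
    table: pd.DataFrame,
    label_col: str = "label",
    positive_label="tumor",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-parameter group means +/- SD, Wilcoxon p-value, significance flag.

    Constant columns are reported with p = 1 and a warning (the rank-sum
    test carries no information there).  No multiple-testing correction is
    applied by default.
    """
    is_pos, params = _split_groups(table, label_col, positive_label)
    rows = []
    for name in params:
        v = table[name].to_numpy(dtype=float)
        if np.any(~np.isfinite(v)):
            raise ValueError(f"parameter {name!r} contains non-finite values")
        x, y = v[is_pos], v[~is_pos]
        if np.all(v == v[0]):
            warnings.warn(f"parameter {name!r} is constant; p set to 1")
            p = 1.0
        else:
            _, p = wilcoxon_rank_sum(x, y)
        rows.append(
            {
                "parameter": name,
                "mean_positive": x.mean(),
                "sd_positive": x.std(ddof=1),
                "mean_negative": y.mean(),
                "sd_negative": y.std(ddof=1),
                "p_value": p,
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def roc_report(
    table: pd.DataFrame,
    label_col: str = "label",
    positive_label="tumor",
) -> pd.DataFrame:
    """Per-parameter diagnostic table: cutoff, sens/spec/PPV/NPV (%), AUC."""
    is_pos, params = _split_groups(table, label_col, positive_label)
    rows = []
    for name in params:
        v = table[name].to_numpy(dtype=float)
        if np.all(v == v[0]):
            warnings.warn(f"parameter {name!r} is constant; skipped in ROC report")
            continue
        roc = roc_curve(v, is_pos)
        cm = optimal_cutoff(roc)
        rows.append(
            {
                "parameter": name,
                "cutoff": cm.cutoff,
                "rule": cm.rule,
                "sensitivity_pct": 100.0 * cm.sensitivity,
                "specificity_pct": 100.0 * cm.specificity,
                "ppv_pct": 100.0 * cm.ppv,
                "npv_pct": 100.0 * cm.npv,
                "accuracy_pct": 100.0 * cm.accuracy,
                "auc": roc.auc,
                "orientation": roc.orientation,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
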