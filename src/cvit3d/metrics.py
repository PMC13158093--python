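"""Evaluation metrics and cohort statistics.

AUC is the rank-statistic (Mann-Whitney) form with midranks for ties:
``AUC = (sum of positive-sample ranks - M(M+1)/2) / (M*N)``.  Correlated
ROC curves are compared with the fast DeLong procedure (structural
components of the Mann-Whitney kernel).  Categorical cohort differences use
the Pearson chi-square test (no Yates correction by default), continuous
ones Welch's unequal-variance t-test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ScoredPredictions:
    """Continuous scores with binary labels (1 = positive / high grade)."""

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float).ravel()
        self.labels = np.asarray(self.labels).ravel().astype(int)
        if self.scores.shape != self.labels.shape:
            raise ValueError("scores and labels differ in length")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")

    @property
    def M(self) -> int:
        return int(self.labels.sum())

    @property
    def N(self) -> int:
        return int(len(self.labels) - self.labels.sum())

    @property
    def midranks(self) -> np.ndarray:
        return stats.rankdata(self.scores, method="average")


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        for f in ("TP", "TN", "FP", "FN"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


# ---------------------------------------------------------------------------
# AUC and threshold metrics
# ---------------------------------------------------------------------------

def auc_rank(pred: ScoredPredictions) -> float:
    """Rank-form AUC with midranks for ties; errors on single-class input."""
    m, n = pred.M, pred.N
    if m < 1 or n < 1:
        raise ValueError("AUC undefined: need at least one sample per class")
    rank_sum = pred.midranks[pred.labels == 1].sum()
    return float((rank_sum - m * (m + 1) / 2.0) / (m * n))


def classification_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, precision, recall, F1.  A zero denominator yields NaN (with
    a warning), never a silent 0."""
    out: dict[str, float] = {}

    def safe(name, num, den):
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator)", stacklevel=3)
            return float("nan")
        return num / den

    out["accuracy"] = safe("accuracy", c.TP + c.TN, c.total)
    out["precision"] = safe("precision", c.TP, c.TP + c.FP)
    out["recall"] = safe("recall", c.TP, c.TP + c.FN)
    p, r = out["precision"], out["recall"]
    if math.isnan(p) or math.isnan(r) or p + r == 0:
        if not (math.isnan(p) or math.isnan(r)):
            warnings.warn("F1 undefined (precision + recall = 0)", stacklevel=2)
        out["f1"] = float("nan")
    else:
        out["f1"] = 2 * p * r / (p + r)
    return out


def threshold_confusion(pred: ScoredPredictions,
                        threshold: float = 0.5) -> ConfusionCounts:
    """Score >= threshold predicts positive."""
    hat = pred.scores >= threshold
    y = pred.labels.astype(bool)
    return ConfusionCounts(
        TP=int((hat & y).sum()),
        TN=int((~hat & ~y).sum()),
        FP=int((hat & ~y).sum()),
        FN=int((~hat & y).sum()),
    )


# ---------------------------------------------------------------------------
# DeLong test
# ---------------------------------------------------------------------------

def _structural_components(pred: ScoredPredictions) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus the V10 (per-positive) and V01 (per-negative) components."""
    pos = pred.labels == 1
    scores = pred.scores
    m, n = pred.M, pred.N
    r_all = stats.rankdata(scores, method="average")
    r_pos = stats.rankdata(scores[pos], method="average")
    r_neg = stats.rankdata(scores[~pos], method="average")
    auc = (r_all[pos].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (r_all[pos] - r_pos) / n            # per positive sample
    v01 = 1.0 - (r_all[~pos] - r_neg) / m     # per negative sample
    return float(auc), v10, v01


def delong_test(pred_a: ScoredPredictions,
                pred_b: ScoredPredictions) -> dict[str, float]:
    """Two-sided DeLong comparison of two correlated AUCs.

    Both score vectors must be over the same samples/labels.  Degenerate
    (zero-variance) differences report z = 0, p = 1.
    """
    if not np.array_equal(pred_a.labels, pred_b.labels):
        raise ValueError("DeLong test requires identical samples and labels")
    auc_a, v10_a, v01_a = _structural_components(pred_a)
    auc_b, v10_b, v01_b = _structural_components(pred_b)
    m, n = pred_a.M, pred_a.N
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    delta = auc_a - auc_b
    if var <= 0 or not np.isfinite(var):
        z = 0.0
        p = 1.0
    else:
        z = delta / math.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
    return {"aucA": auc_a, "aucB": auc_b, "delta": delta, "z": z, "p": p}


# ---------------------------------------------------------------------------
# cohort statistics
# ---------------------------------------------------------------------------

def chi_square_test(table: np.ndarray, yates: bool = False) -> dict[str, float]:
    """Pearson chi-square on an r x c contingency table.

    Yates continuity correction is off by default and only applies to 2x2
    tables.
    """
    table = np.asarray(table)
    if table.ndim != 2 or table.min() < 0:
        raise ValueError("need a 2-D table of nonnegative counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero row or column total")
    stat, p, df, expected = stats.chi2_contingency(table, correction=yates)
    if (expected <= 0).any():
        raise ValueError("expected count <= 0")
    return {"stat": float(stat), "df": int(df), "p": float(p)}


def welch_t_test(a: np.ndarray, b: np.ndarray) -> dict[str, float]:
    """Welch (unequal-variance) two-sided t-test with Satterthwaite df."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        return {"t": 0.0, "df": float(len(a) + len(b) - 2), "p": 1.0}
    res = stats.ttest_ind(a, b, equal_var=False)
    return {"t": float(res.statistic), "df": float(res.df), "p": float(res.pvalue)}


def cohort_summary(table: pd.DataFrame, categorical: list[str],
                   group: str | None = None) -> dict:
    """Per-category n (%) summaries, percentages rounded to 1 decimal.

    Returns ``{column: {category: {"n": int, "pct": float}}}`` overall and,
    when ``group`` names a column, the same nested per group level.
    """
    if len(table) == 0:
        raise ValueError("empty cohort table")

    def tally(df: pd.DataFrame) -> dict:
        out = {}
        for col in categorical:
            counts = df[col].value_counts()
            total = int(counts.sum())
            out[col] = {str(k): {"n": int(v), "pct": round(100.0 * v / total, 1)}
                        for k, v in counts.items()}
        return out

    result = {"overall": tally(table), "n": int(len(table))}
    if group is not None:
        result["by_group"] = {str(g): tally(df)
                              for g, df in table.groupby(group, observed=True)}
    return result


def metrics_report(pred: ScoredPredictions, threshold: float = 0.5) -> dict:
    """JSON-ready bundle: AUC + thresholded confusion metrics + ROC points."""
    conf = threshold_confusion(pred, threshold)
    rep = {"auc": auc_rank(pred), "threshold": threshold,
           "confusion": {"TP": conf.TP, "TN": conf.TN,
                         "FP": conf.FP, "FN": conf.FN}}
    rep.update(classification_metrics(conf))
    cuts = np.r_[np.inf, np.unique(pred.scores)[::-1]]
    roc = []
    for c in cuts:
        cc = threshold_confusion(pred, c)
        tpr = cc.TP / max(cc.TP + cc.FN, 1)
        fpr = cc.FP / max(cc.FP + cc.TN, 1)
        roc.append({"threshold": float(c), "tpr": tpr, "fpr": fpr})
    rep["roc"] = roc
    return rep
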