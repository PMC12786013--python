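"""Clinical evaluation statistics: confusion-matrix metrics, Mann-Whitney
AUC, bootstrap confidence intervals, exact McNemar and DeLong paired tests,
Brier score with reliability curves, and decision-curve analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn == 0:
            raise ValueError("confusion matrix is empty")

    @classmethod
    def from_predictions(cls, predicted, labels) -> "ConfusionCounts":
        p = np.asarray(predicted, dtype=int)
        y = np.asarray(labels, dtype=int)
        return cls(
            tp=int(((p == 1) & (y == 1)).sum()),
            fp=int(((p == 1) & (y == 0)).sum()),
            tn=int(((p == 0) & (y == 0)).sum()),
            fn=int(((p == 0) & (y == 1)).sum()),
        )


@dataclass
class MetricReport:
    accuracy: float
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    f1: float | None
    auc: float | None = None
    ci: dict = field(default_factory=dict)  # metric name -> (lower, upper)


@dataclass
class ComparisonResult:
    test: str  # 'mcnemar' or 'delong'
    statistic: float
    p_value: float
    ancillary: dict = field(default_factory=dict)


def _safe_div(num, den):
    return num / den if den > 0 else None


def confusion_metrics(counts: ConfusionCounts) -> MetricReport:
    """Point metrics from a confusion matrix.

    Metrics with a zero denominator are reported as ``None`` (undefined)
    rather than 0; F1 with undefined precision/recall degrades to 0 with a
    warning when one of them is defined and zero.
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    total = tp + fp + tn + fn
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    specificity = _safe_div(tn, tn + fp)
    accuracy = (tp + tn) / total
    if precision is None or recall is None:
        f1 = None
    elif precision + recall == 0:
        logger.warning("F1 undefined (precision = recall = 0); reporting 0 by convention")
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricReport(
        accuracy=accuracy,
        sensitivity=recall,
        specificity=specificity,
        precision=precision,
        f1=f1,
    )


def auc_mann_whitney(scores, labels) -> float:
    """AUC as the Mann-Whitney concordance probability (ties credited 0.5)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(s)  # average ranks handle ties
    r_pos = ranks[y == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def bootstrap_ci(
    metric_fn,
    scores,
    labels,
    n_boot: int = 1000,
    seed: int = 42,
    alpha: float = 0.05,
):
    """Case-level percentile bootstrap CI for ``metric_fn(scores, labels)``.

    Replicates that draw a single class (where the metric is undefined) are
    redrawn, with a log notice.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    n = len(y)
    values = np.empty(n_boot)
    redraws = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            if 0 < y[idx].sum() < n:
                break
            redraws += 1
        values[b] = metric_fn(s[idx], y[idx])
    if redraws:
        logger.info("redrew %d single-class bootstrap replicates", redraws)
    lower, upper = np.percentile(values, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lower), float(upper)


def mcnemar_test(correct_a, correct_b, exact: bool = True) -> ComparisonResult:
    """Paired McNemar test on per-case correctness of two classifiers.

    Exact two-sided binomial on the discordant counts by default (suited to
    small test sets); ``exact=False`` uses the chi-square approximation with
    continuity correction.
    """
    a = np.asarray(correct_a, dtype=bool)
    b_arr = np.asarray(correct_b, dtype=bool)
    if a.shape != b_arr.shape:
        raise ValueError("paired vectors must have equal length")
    b = int((a & ~b_arr).sum())  # A right, B wrong
    c = int((~a & b_arr).sum())  # A wrong, B right
    if b + c == 0:
        logger.warning("no discordant pairs; McNemar p = 1.0")
        return ComparisonResult("mcnemar", 0.0, 1.0, {"b": b, "c": c})
    if exact:
        res = stats.binomtest(b, b + c, 0.5, alternative="two-sided")
        return ComparisonResult("mcnemar", float(b), float(res.pvalue), {"b": b, "c": c})
    chi2 = (abs(b - c) - 1) ** 2 / (b + c)
    p = float(stats.chi2.sf(chi2, df=1))
    return ComparisonResult("mcnemar", float(chi2), p, {"b": b, "c": c})


def _placements(scores, labels):
    """DeLong placement values: V10 (per positive), V01 (per negative)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos, neg = s[y == 1], s[y == 0]
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / len(neg) for p in pos])
    v01 = np.array([(np.sum(pos > n) + 0.5 * np.sum(pos == n)) / len(pos) for n in neg])
    return v10, v01


def delong_test(scores_a, scores_b, labels) -> ComparisonResult:
    """DeLong's test for two correlated AUCs computed on the same cases."""
    y = np.asarray(labels, dtype=int)
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise ValueError("DeLong test requires both classes present")
    auc_a = auc_mann_whitney(scores_a, y)
    auc_b = auc_mann_whitney(scores_b, y)
    v10a, v01a = _placements(scores_a, y)
    v10b, v01b = _placements(scores_b, y)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.stack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    delta = auc_a - auc_b
    if var <= 0:
        if abs(delta) < 1e-12:
            return ComparisonResult(
                "delong", 0.0, 1.0, {"delta_auc": 0.0, "auc_a": auc_a, "auc_b": auc_b}
            )
        logger.warning("zero DeLong variance with nonzero AUC difference; p undefined")
        return ComparisonResult(
            "delong",
            np.inf if delta > 0 else -np.inf,
            float("nan"),
            {"delta_auc": delta, "auc_a": auc_a, "auc_b": auc_b},
        )
    z = delta / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return ComparisonResult(
        "delong", float(z), float(p), {"delta_auc": float(delta), "auc_a": auc_a, "auc_b": auc_b}
    )


def brier_and_calibration(probabilities, labels, n_bins: int = 10):
    """Brier score and an equal-width reliability table.

    Returns (brier, DataFrame with bin, n, mean_predicted, observed_rate);
    empty bins are omitted from the table.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    brier = float(np.mean((p - y) ** 2))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    bin_idx = np.clip(np.digitize(p, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        m = bin_idx == b
        if not m.any():
            continue
        rows.append(
            {
                "bin": b,
                "n": int(m.sum()),
                "mean_predicted": float(p[m].mean()),
                "observed_rate": float(y[m].mean()),
            }
        )
    return brier, pd.DataFrame(rows)


def decision_curve(
    probabilities,
    labels,
    thresholds=None,
) -> pd.DataFrame:
    """Net-benefit table for the model, treat-all and treat-none strategies.

    NB(t) = TP/N - (FP/N) * t / (1 - t), classifying positive at p >= t.
    Default threshold grid: 0.05 to 0.50 in steps of 0.01.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if thresholds is None:
        thresholds = np.round(np.arange(0.05, 0.50 + 1e-9, 0.01), 4)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(thresholds <= 0) or np.any(thresholds >= 1):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = len(y)
    n_pos = y.sum()
    rows = []
    for t in thresholds:
        pred = p >= t
        tp = int((pred & (y == 1)).sum())
        fp = int((pred & (y == 0)).sum())
        odds = t / (1.0 - t)
        rows.append(
            {
                "threshold": t,
                "net_benefit_model": tp / n - (fp / n) * odds,
                "net_benefit_all": n_pos / n - ((n - n_pos) / n) * odds,
                "net_benefit_none": 0.0,
            }
        )
    return pd.DataFrame(rows)


def metric_report(
    scores,
    labels,
    threshold: float = 0.5,
    n_boot: int = 1000,
    seed: int = 42,
    with_ci: bool = True,
) -> MetricReport:
    """Full report: thresholded confusion metrics + AUC, with bootstrap CIs."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    counts = ConfusionCounts.from_predictions((s >= threshold).astype(int), y)
    report = confusion_metrics(counts)
    report.auc = auc_mann_whitney(s, y)
    if with_ci:
        report.ci["auc"] = bootstrap_ci(auc_mann_whitney, s, y, n_boot=n_boot, seed=seed)
        report.ci["accuracy"] = bootstrap_ci(
            lambda sc, yy: float(((sc >= threshold).astype(int) == yy).mean()),
            s,
            y,
            n_boot=n_boot,
            seed=seed + 1,
        )
    return report
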