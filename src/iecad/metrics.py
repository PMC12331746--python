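"""Evaluation metrics: Dice, MAE, Pearson, ROC/AUC, the confusion-matrix
panel, and subject-level percentile-bootstrap confidence intervals.

Standard statistics are delegated to scipy / scikit-learn; this module owns
the report plumbing (undefined ratios stay NaN rather than being silently
zeroed) and the bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr
from sklearn.metrics import roc_auc_score

__all__ = ["MetricReport", "dice", "mae", "pearson", "roc_auc",
           "classification_report", "bootstrap_ci"]


@dataclass(frozen=True)
class MetricReport:
    name: str
    value: float
    ci_low: float | None = None
    ci_high: float | None = None
    n: int | None = None

    def __str__(self) -> str:
        s = f"{self.name}: {self.value:.3f}"
        if self.ci_low is not None:
            s += f" ({self.ci_low:.3f}, {self.ci_high:.3f})"
        return s


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|) of two binary masks.

    Defined as 1 when both masks are empty.
    """
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"mask grids differ: {pred.shape} vs {truth.shape}")
    denom = pred.sum() + truth.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(pred, truth).sum() / denom)


def mae(pred, truth) -> float:
    """Mean absolute error."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.size == 0:
        raise ValueError("inputs must be equal-length and non-empty")
    return float(np.mean(np.abs(pred - truth)))


def pearson(x, y) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or x.shape != y.shape:
        raise ValueError("need two equal-length samples of size >= 2")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(pearsonr(x, y).statistic)


def roc_auc(scores, labels) -> float:
    """AUC: probability a random positive outscores a random negative
    (ties count one half)."""
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present for ROC analysis")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def classification_report(pred, truth) -> dict[str, MetricReport]:
    """Accuracy, precision, sensitivity, specificity and F1 from binaries.

    Ratios with zero denominator are reported as NaN, not 0.
    """
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape or pred.size == 0:
        raise ValueError("predictions and truth must be equal-length, non-empty")
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    n = pred.size

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    precision = ratio(tp, tp + fp)
    sensitivity = ratio(tp, tp + fn)
    f1 = (2 * precision * sensitivity / (precision + sensitivity)
          if precision + sensitivity > 0 else float("nan"))
    values = {
        "accuracy": (tp + tn) / n,
        "precision": precision,
        "sensitivity": sensitivity,
        "specificity": ratio(tn, tn + fp),
        "f1": f1,
    }
    return {k: MetricReport(name=k, value=float(v), n=n)
            for k, v in values.items()}


def bootstrap_ci(metric_fn, data, n_boot: int = 1000, seed: int = 0,
                 level: float = 0.95) -> tuple[float, float, int]:
    """Subject-level percentile bootstrap.

    ``metric_fn(subset)`` computes the statistic on a list of subjects;
    resamples raising ValueError (e.g. single-class draws) are skipped and
    counted.  Returns (low, high, n_skipped).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    data = list(data)
    rng = np.random.default_rng(seed)
    stats = []
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, len(data), size=len(data))
        try:
            stats.append(metric_fn([data[i] for i in idx]))
        except ValueError:
            skipped += 1
    if not stats:
        raise ValueError("every bootstrap resample was degenerate")
    lo, hi = np.percentile(stats, [100 * (1 - level) / 2,
                                   100 * (1 + level) / 2])
    return float(lo), float(hi), skipped
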