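"""Classification metrics, confusion matrices and 95% confidence intervals.

Per-class precision/recall/F1 come from one-vs-rest counts on the 6x6
confusion matrix; macro aggregates weight classes equally and weighted
aggregates weight by support. The 95% interval on a metric across n
repeated experiments is the normal-quantile form x_bar +/- 1.96 s / sqrt(n)
with the sample (n-1) standard deviation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support as _sk_prfs

from .containers import N_CLASSES

logger = logging.getLogger(__name__)

__all__ = [
    "MetricsReport",
    "confusion_and_metrics",
    "IntervalEstimate",
    "ci95",
    "aggregate_reports",
    "format_mean_sd_ci",
]


@dataclass
class MetricsReport:
    """Full metric suite for one evaluation run."""

    accuracy: float
    precision: np.ndarray  # per class
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    confusion: np.ndarray  # counts, (n_classes, n_classes)
    n_test: int
    zero_support_classes: tuple[int, ...] = ()

    @property
    def confusion_normalized(self) -> np.ndarray:
        """Row-normalized confusion matrix; rows without support stay zero."""
        counts = self.confusion.astype(np.float64)
        row = counts.sum(axis=1, keepdims=True)
        return np.divide(counts, row, out=np.zeros_like(counts), where=row > 0)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1": self.f1.tolist(),
            "support": self.support.tolist(),
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "weighted_precision": self.weighted_precision,
            "weighted_recall": self.weighted_recall,
            "weighted_f1": self.weighted_f1,
            "confusion": self.confusion.tolist(),
            "n_test": self.n_test,
        }


def confusion_and_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, n_classes: int = N_CLASSES
) -> MetricsReport:
    """Compute the full metric suite from true and predicted label sequences.

    Classes with zero predicted positives get precision 0 (flagged in
    ``zero_support_classes``) rather than being dropped, so macro averages
    stay defined on degenerate runs.
    """
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or len(y_true) == 0:
        raise ValueError("y_true and y_pred must be equal-length 1-D, length >= 1")
    if y_true.min() < 0 or y_true.max() >= n_classes or y_pred.min() < 0 or y_pred.max() >= n_classes:
        raise ValueError(f"labels must lie in 0..{n_classes - 1}")
    labels = np.arange(n_classes)
    conf = _sk_confusion(y_true, y_pred, labels=labels)
    prec, rec, f1, support = _sk_prfs(
        y_true, y_pred, labels=labels, zero_division=0, average=None
    )
    zero_pred = tuple(int(c) for c in labels if conf[:, c].sum() == 0)
    if zero_pred:
        logger.info("classes never predicted (precision set to 0): %s", zero_pred)
    macro_p, macro_r, macro_f, _ = _sk_prfs(
        y_true, y_pred, labels=labels, zero_division=0, average="macro"
    )
    w_p, w_r, w_f, _ = _sk_prfs(
        y_true, y_pred, labels=labels, zero_division=0, average="weighted"
    )
    return MetricsReport(
        accuracy=float((y_true == y_pred).mean()),
        precision=prec,
        recall=rec,
        f1=f1,
        support=support,
        macro_precision=float(macro_p),
        macro_recall=float(macro_r),
        macro_f1=float(macro_f),
        weighted_precision=float(w_p),
        weighted_recall=float(w_r),
        weighted_f1=float(w_f),
        confusion=conf,
        n_test=int(len(y_true)),
        zero_support_classes=zero_pred,
    )


@dataclass
class IntervalEstimate:
    """Mean, sample SD and normal-quantile 95% half-width over n values."""

    mean: float
    sd: float
    n: int
    half_width: float = field(init=False)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        self.half_width = 1.96 * self.sd / np.sqrt(self.n)


def ci95(values) -> IntervalEstimate:
    """95% CI of repeated metric values: x_bar +/- 1.96 s / sqrt(n), sample SD."""
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 1 or len(values) < 2:
        raise ValueError("ci95 needs a 1-D sequence of at least 2 values")
    return IntervalEstimate(
        mean=float(values.mean()), sd=float(values.std(ddof=1)), n=len(values)
    )


_SUMMARY_METRICS = ("accuracy", "macro_precision", "macro_recall", "macro_f1")


def aggregate_reports(reports: list[MetricsReport]) -> dict[str, IntervalEstimate]:
    """Mean +/- SD with 95% CI per aggregate metric across repeated runs."""
    if len(reports) < 2:
        raise ValueError("aggregation needs at least 2 reports")
    return {
        m: ci95([getattr(r, m) for r in reports]) for m in _SUMMARY_METRICS
    }


def format_mean_sd_ci(est: IntervalEstimate) -> str:
    """Render one cell as "mean ± sd (±ci)", the benchmark's table style."""
    return f"{est.mean:.3f} ± {est.sd:.4f} (±{est.half_width:.4f})"
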