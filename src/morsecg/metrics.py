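"""Multi-class confusion matrix and one-vs-rest evaluation metrics.

Conventions: the confusion matrix stores predictions in rows and actual
classes in columns, ``counts[p][a]`` = number of items predicted as class p
whose actual class is a.  Per-class counts treat one class as positive and
the rest as negative; from them

    sensitivity = recall = TP / (TP + FN)
    precision             = TP / (TP + FP)
    specificity           = TN / (TN + FP)
    F-measure             = 2 * precision * recall / (precision + recall)

each reported as a percentage, and overall accuracy is 100 * trace / total.
Metrics are computed from raw counts and rounded only for display; zero
denominators yield NaN (with a warning) and are excluded from macro
averages rather than silently reported as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "OneVsRestCounts",
    "MetricsReport",
    "confusion_matrix",
    "one_vs_rest",
    "compute_metrics",
    "overall_accuracy",
    "macro_average",
    "evaluate",
    "report_from_matrix",
]

METRIC_NAMES = ("sensitivity", "specificity", "precision", "recall", "f_measure")


@dataclass
class ConfusionMatrix:
    """K x K prediction counts; rows = predicted class, columns = actual class."""

    counts: np.ndarray
    class_order: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_order)
        if self.counts.shape != (k, k):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match {k} classes"
            )
        if (self.counts < 0).any():
            raise ValueError("confusion matrix entries must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=[f"pred_{c}" for c in self.class_order],
            columns=[f"actual_{c}" for c in self.class_order],
        )


@dataclass(frozen=True)
class OneVsRestCounts:
    """TP/TN/FP/FN for one class taken as positive against the rest."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """Per-class metrics (percent), overall accuracy, and macro averages."""

    class_order: list[str]
    per_class: dict[str, dict[str, float]]
    per_class_counts: dict[str, OneVsRestCounts]
    overall_accuracy: float
    macro: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Human-readable table: Class, TP, TN, FP, FN, Se, Sp, Pr, Re, F1."""
        rows = []
        for c in self.class_order:
            cnt = self.per_class_counts[c]
            m = self.per_class[c]
            rows.append(
                {
                    "Class": c,
                    "TP": cnt.tp,
                    "TN": cnt.tn,
                    "FP": cnt.fp,
                    "FN": cnt.fn,
                    "Se": round(m["sensitivity"], 1),
                    "Sp": round(m["specificity"], 1),
                    "Pr": round(m["precision"], 1),
                    "Re": round(m["recall"], 1),
                    "F1": round(m["f_measure"], 1),
                }
            )
        rows.append(
            {
                "Class": "Avg",
                "TP": "",
                "TN": "",
                "FP": "",
                "FN": "",
                **{
                    abbr: round(self.macro[name], 1)
                    for abbr, name in zip(("Se", "Sp", "Pr", "Re", "F1"), METRIC_NAMES)
                },
            }
        )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "class_order": list(self.class_order),
            "overall_accuracy": self.overall_accuracy,
            "per_class": {
                c: {
                    **{k: v for k, v in self.per_class[c].items()},
                    "tp": self.per_class_counts[c].tp,
                    "tn": self.per_class_counts[c].tn,
                    "fp": self.per_class_counts[c].fp,
                    "fn": self.per_class_counts[c].fn,
                }
                for c in self.class_order
            },
            "macro": dict(self.macro),
        }


def confusion_matrix(y_true, y_pred, class_order: list[str]) -> ConfusionMatrix:
    """Count predictions into a K x K matrix (rows predicted, columns actual)."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted")
    if not y_true:
        raise ValueError("empty inputs: nothing to evaluate")
    idx = {c: i for i, c in enumerate(class_order)}
    counts = np.zeros((len(class_order), len(class_order)), dtype=int)
    for t, p in zip(y_true, y_pred):
        if t not in idx:
            raise ValueError(f"unknown actual label {t!r}; class_order is {class_order}")
        if p not in idx:
            raise ValueError(f"unknown predicted label {p!r}; class_order is {class_order}")
        counts[idx[p], idx[t]] += 1
    return ConfusionMatrix(counts=counts, class_order=list(class_order))


def one_vs_rest(cm: ConfusionMatrix, cls: str) -> OneVsRestCounts:
    """Per-class TP/TN/FP/FN from the multi-class matrix."""
    if cls not in cm.class_order:
        raise ValueError(f"unknown class {cls!r}; class_order is {cm.class_order}")
    c = cm.class_order.index(cls)
    tp = int(cm.counts[c, c])
    fn = int(cm.counts[:, c].sum()) - tp  # actual-c items predicted elsewhere
    fp = int(cm.counts[c, :].sum()) - tp  # predicted-c items actually other
    tn = cm.total - tp - fn - fp
    return OneVsRestCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio_pct(num: int, den: int, name: str, cls: str = "") -> float:
    if den == 0:
        warnings.warn(
            f"{name}{' for class ' + cls if cls else ''} undefined "
            "(zero denominator); reporting NaN",
            stacklevel=3,
        )
        return float("nan")
    return 100.0 * num / den


def compute_metrics(counts: OneVsRestCounts, cls: str = "") -> dict[str, float]:
    """Sensitivity, specificity, precision, recall, F-measure (percent).

    Sensitivity and recall are the same ratio and are reported under both
    names.  Values come from raw counts; round only for display.
    """
    se = _ratio_pct(counts.tp, counts.tp + counts.fn, "sensitivity", cls)
    sp = _ratio_pct(counts.tn, counts.tn + counts.fp, "specificity", cls)
    pr = _ratio_pct(counts.tp, counts.tp + counts.fp, "precision", cls)
    if np.isnan(pr) or np.isnan(se) or pr + se == 0:
        f1 = float("nan")
        if not (np.isnan(pr) or np.isnan(se)):
            warnings.warn(
                f"F-measure{' for class ' + cls if cls else ''} undefined; reporting NaN",
                stacklevel=2,
            )
    else:
        f1 = 2.0 * pr * se / (pr + se)
    return {
        "sensitivity": se,
        "specificity": sp,
        "precision": pr,
        "recall": se,
        "f_measure": f1,
    }


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """100 * (sum of the diagonal) / total; permutation-invariant."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix: overall accuracy undefined")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def macro_average(per_class_reports: dict[str, dict[str, float]]) -> dict[str, float]:
    """Unweighted mean of each metric over classes, from unrounded values.

    NaN (undefined) per-class entries are excluded from the average for
    that metric, with a warning.
    """
    if not per_class_reports:
        raise ValueError("need at least one class report")
    out = {}
    for name in METRIC_NAMES:
        vals = np.array([m[name] for m in per_class_reports.values()])
        ok = ~np.isnan(vals)
        if not ok.all():
            warnings.warn(
                f"macro {name}: excluding {int((~ok).sum())} undefined class value(s)",
                stacklevel=2,
            )
        out[name] = float(vals[ok].mean()) if ok.any() else float("nan")
    return out


def evaluate(y_true, y_pred, class_order: list[str]) -> MetricsReport:
    """Full evaluation: confusion matrix -> per-class metrics -> macro averages."""
    cm = confusion_matrix(y_true, y_pred, class_order)
    return report_from_matrix(cm)


def report_from_matrix(cm: ConfusionMatrix) -> MetricsReport:
    per_class_counts = {c: one_vs_rest(cm, c) for c in cm.class_order}
    per_class = {c: compute_metrics(per_class_counts[c], c) for c in cm.class_order}
    return MetricsReport(
        class_order=list(cm.class_order),
        per_class=per_class,
        per_class_counts=per_class_counts,
        overall_accuracy=overall_accuracy(cm),
        macro=macro_average(per_class),
    )
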