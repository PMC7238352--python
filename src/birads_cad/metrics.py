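"""Confusion matrix and evaluation metrics for the four BI-RADS classes.

Rows of the confusion matrix are actual classes, columns predicted, in
the fixed order B-2, B-3, B-4, B-5.  Accuracy is the trace over the
total; sensitivity and specificity are one-vs-rest per class; PPV, NPV
and the Matthews correlation coefficient are micro-averaged: the
one-vs-rest TP, FP, FN, TN counts are summed across the four classes
before the rates are computed.  For any single-label multi-class matrix
the micro-averaged PPV equals the overall accuracy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .feature_table import LABELS

DISPLAY_LABELS = ("B-2", "B-3", "B-4", "B-5")
_INDEX = {lab: i for i, lab in enumerate(LABELS)}
_INDEX.update({lab: i for i, lab in enumerate(DISPLAY_LABELS)})


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (4, 4) rows = actual, cols = predicted

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (4, 4) or (self.counts < 0).any():
            raise ValueError("confusion matrix must be 4x4 with non-negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, k: int) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) counts for class index k."""
        tp = int(self.counts[k, k])
        fp = int(self.counts[:, k].sum() - tp)
        fn = int(self.counts[k, :].sum() - tp)
        tn = self.total - tp - fp - fn
        return tp, fp, fn, tn

    def to_csv(self, path: str) -> None:
        pd.DataFrame(self.counts, index=DISPLAY_LABELS, columns=DISPLAY_LABELS).to_csv(
            path, index_label="actual\\predicted"
        )


def confusion(actual, predicted) -> ConfusionMatrix:
    """Count actual-vs-predicted label pairs over the four classes."""
    actual = list(actual)
    predicted = list(predicted)
    if len(actual) != len(predicted):
        raise ValueError("label sequences must have equal length")
    counts = np.zeros((4, 4), dtype=int)
    for a, p in zip(actual, predicted):
        if a not in _INDEX or p not in _INDEX:
            raise ValueError(f"unknown label in pair ({a!r}, {p!r})")
        counts[_INDEX[a], _INDEX[p]] += 1
    return ConfusionMatrix(counts)


def accuracy(cm: ConfusionMatrix) -> float:
    """Correct predictions (the diagonal) over the total case count."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.total


def per_class_rates(cm: ConfusionMatrix) -> dict[str, dict[str, float | None]]:
    """One-vs-rest sensitivity and specificity per BI-RADS class."""
    out: dict[str, dict[str, float | None]] = {}
    for k, lab in enumerate(DISPLAY_LABELS):
        tp, fp, fn, tn = cm.one_vs_rest(k)
        sens = tp / (tp + fn) if (tp + fn) > 0 else None
        spec = tn / (tn + fp) if (tn + fp) > 0 else None
        out[lab] = {
            "sensitivity": sens,
            "specificity": spec,
            "tp": tp,
            "fp": fp,
            "fn": fn,
            "tn": tn,
        }
    return out


def micro_metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """Micro-averaged (PPV, NPV, MCC) from summed one-vs-rest counts."""
    tp = fp = fn = tn = 0
    for k in range(4):
        a, b, c, d = cm.one_vs_rest(k)
        tp, fp, fn, tn = tp + a, fp + b, fn + c, tn + d
    ppv = tp / (tp + fp) if tp + fp else 0.0
    npv = tn / (tn + fn) if tn + fn else 0.0
    denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / denom
    return float(ppv), float(npv), float(mcc)


@dataclass
class MetricsReport:
    confusion_matrix: ConfusionMatrix
    accuracy: float
    per_class: dict[str, dict[str, float | None]]
    micro_ppv: float
    micro_npv: float
    micro_mcc: float

    def to_dict(self) -> dict:
        def pct(x):
            return None if x is None else round(100.0 * x, 1)

        return {
            "confusion_matrix": self.confusion_matrix.counts.tolist(),
            "class_order": list(DISPLAY_LABELS),
            "accuracy": self.accuracy,
            "accuracy_pct": pct(self.accuracy),
            "per_class": {
                lab: {
                    "sensitivity": vals["sensitivity"],
                    "sensitivity_pct": pct(vals["sensitivity"]),
                    "specificity": vals["specificity"],
                    "specificity_pct": pct(vals["specificity"]),
                    "tp": vals["tp"],
                    "fp": vals["fp"],
                    "fn": vals["fn"],
                    "tn": vals["tn"],
                }
                for lab, vals in self.per_class.items()
            },
            "micro": {
                "ppv": self.micro_ppv,
                "ppv_pct": pct(self.micro_ppv),
                "npv": self.micro_npv,
                "npv_pct": pct(self.micro_npv),
                "mcc": self.micro_mcc,
                "mcc_pct": pct(self.micro_mcc),
            },
        }

    def to_json(self, path: str | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def evaluate(actual, predicted) -> MetricsReport:
    """Full evaluation report from actual and predicted label sequences."""
    cm = confusion(actual, predicted)
    ppv, npv, mcc = micro_metrics(cm)
    return MetricsReport(
        confusion_matrix=cm,
        accuracy=accuracy(cm),
        per_class=per_class_rates(cm),
        micro_ppv=ppv,
        micro_npv=npv,
        micro_mcc=mcc,
    )
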