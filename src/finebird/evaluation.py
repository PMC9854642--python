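"""Multi-class accuracy / precision / recall / F1 from one-vs-rest counts.

Per-class counts are one-vs-rest: for class k, TP = samples of k predicted
k, FP = other samples predicted k, FN = samples of k predicted otherwise.
Summary precision/recall/F1 are macro-averaged (unweighted class means),
matching evenly distributed class sizes; accuracy is the global fraction
correct.  Classes with an empty denominator get 0 and a flag.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConfusionCounts", "MetricsReport", "confusion_from_predictions", "metrics_report"]


@dataclass
class ConfusionCounts:
    """One-vs-rest tp/fp/fn/tn per class, plus the sample total."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray
    n_samples: int

    @property
    def n_classes(self) -> int:
        return len(self.tp)


@dataclass
class MetricsReport:
    """Summary metrics plus the per-class table behind them."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    per_class: list[dict] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "accuracy": self.accuracy,
                    "precision": self.precision,
                    "recall": self.recall,
                    "f1": self.f1,
                    "per_class": self.per_class,
                },
                fh,
                indent=2,
            )

    def to_csv(self, path) -> None:
        cols = ["class", "tp", "fp", "fn", "tn", "precision", "recall", "f1", "degenerate"]
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=cols)
            writer.writeheader()
            writer.writerows(self.per_class)
            writer.writerow(
                {
                    "class": "macro",
                    "precision": self.precision,
                    "recall": self.recall,
                    "f1": self.f1,
                    "degenerate": "",
                    "tp": "",
                    "fp": "",
                    "fn": "",
                    "tn": "",
                }
            )


def confusion_from_predictions(labels, preds, n_classes: int) -> ConfusionCounts:
    """Tally one-vs-rest counts for every class from paired label/prediction lists."""
    labels = np.asarray(labels, dtype=np.int64)
    preds = np.asarray(preds, dtype=np.int64)
    if labels.shape != preds.shape:
        raise ValueError(f"length mismatch: {labels.shape} labels vs {preds.shape} predictions")
    if labels.size and (labels.min() < 0 or labels.max() >= n_classes
                        or preds.min() < 0 or preds.max() >= n_classes):
        raise ValueError("labels/predictions outside [0, n_classes)")
    n = labels.size
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (labels, preds), 1)
    tp = np.diag(cm).copy()
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    tn = n - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn, n)


def _safe_div(num: np.ndarray, den: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    degenerate = den == 0
    out = np.where(degenerate, 0.0, num / np.where(degenerate, 1, den))
    return out, degenerate


def metrics_report(counts: ConfusionCounts) -> MetricsReport:
    """Accuracy plus macro-averaged precision, recall and F1.

    Accuracy = correct classifications / all classifications; per-class
    P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R); the summary values are
    unweighted means over classes.
    """
    if counts.n_samples == 0:
        raise ValueError("no samples")
    prec, p_deg = _safe_div(counts.tp.astype(float), counts.tp + counts.fp)
    rec, r_deg = _safe_div(counts.tp.astype(float), counts.tp + counts.fn)
    f1, f_deg = _safe_div(2 * prec * rec, prec + rec)
    per_class = [
        {
            "class": k,
            "tp": int(counts.tp[k]),
            "fp": int(counts.fp[k]),
            "fn": int(counts.fn[k]),
            "tn": int(counts.tn[k]),
            "precision": float(prec[k]),
            "recall": float(rec[k]),
            "f1": float(f1[k]),
            "degenerate": bool(p_deg[k] or r_deg[k] or f_deg[k]),
        }
        for k in range(counts.n_classes)
    ]
    accuracy = float(counts.tp.sum() / counts.n_samples)
    return MetricsReport(
        accuracy, float(prec.mean()), float(rec.mean()), float(f1.mean()), per_class
    )
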