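"""Multiclass evaluation: confusion matrices and the SE/SP/F1 metric set.

Sensitivity (= recall, true-positive rate) and specificity (true-negative
rate) are computed one-vs-rest per class and macro-averaged (unweighted class
mean) by default, with micro-averaging available. Zero-denominator rates —
a class absent from the truth or the predictions — are reported as 0 with an
explicit flag so reports stay machine-readable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, ShapeError

__all__ = ["EvalReport", "confusion_matrix", "metrics_from_cm",
           "comparison_table", "save_confusion_png"]


@dataclass
class EvalReport:
    """Confusion matrix plus per-class and aggregate rates."""

    confusion: np.ndarray
    per_class: dict = field(default_factory=dict)   # name/index -> rates dict
    accuracy: float = 0.0
    macro_sensitivity: float = 0.0
    macro_specificity: float = 0.0
    macro_precision: float = 0.0
    macro_f1: float = 0.0
    macro_recall: float = 0.0
    micro_f1: float = 0.0
    zero_division_flags: list = field(default_factory=list)
    class_names: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "confusion": np.asarray(self.confusion).tolist(),
            "per_class": self.per_class,
            "accuracy": self.accuracy,
            "macro_sensitivity": self.macro_sensitivity,
            "macro_specificity": self.macro_specificity,
            "macro_precision": self.macro_precision,
            "macro_f1": self.macro_f1,
            "macro_recall": self.macro_recall,
            "micro_f1": self.micro_f1,
            "zero_division_flags": self.zero_division_flags,
            "class_names": list(self.class_names),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @staticmethod
    def from_json(text_or_path) -> "EvalReport":
        try:
            obj = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                obj = json.load(fh)
        rep = EvalReport(confusion=np.asarray(obj["confusion"], dtype=np.int64))
        for key, val in obj.items():
            if key != "confusion":
                setattr(rep, key, val)
        return rep


def confusion_matrix(true_labels, predicted_labels, num_classes: int) -> np.ndarray:
    """K x K count matrix; entry (i, j) = samples with true class i predicted j."""
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_labels, dtype=np.int64)
    if t.shape != p.shape:
        raise ShapeError(f"label sequences differ in length: {t.shape} vs {p.shape}")
    if len(t) and (t.min() < 0 or t.max() >= num_classes
                   or p.min() < 0 or p.max() >= num_classes):
        raise DataError(f"labels must lie in [0, {num_classes})")
    cm = np.zeros((num_classes, num_classes), dtype=np.int64)
    np.add.at(cm, (t, p), 1)
    return cm


def metrics_from_cm(cm: np.ndarray, class_names=None) -> EvalReport:
    """One-vs-rest sensitivity/specificity/precision/F1 per class + macro averages.

    Per class c: SE = TP/(TP+FN), SP = TN/(TN+FP), precision = TP/(TP+FP),
    F1 = 2 * precision * SE / (precision + SE); accuracy = trace / total.
    """
    cm = np.asarray(cm, dtype=np.int64)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or cm.size == 0:
        raise ShapeError(f"confusion matrix must be square and nonempty, got {cm.shape}")
    total = int(cm.sum())
    if total == 0:
        raise DataError("confusion matrix has no samples")
    k = cm.shape[0]
    names = list(class_names) if class_names is not None else [str(i) for i in range(k)]
    flags = []

    def _rate(num, den, what, cls):
        if den == 0:
            flags.append(f"{what} undefined for class {cls} (zero denominator); reported as 0")
            return 0.0
        return num / den

    report = EvalReport(confusion=cm, class_names=names)
    se_list, sp_list, pr_list, f1_list = [], [], [], []
    for c in range(k):
        tp = int(cm[c, c])
        fn = int(cm[c].sum() - tp)
        fp = int(cm[:, c].sum() - tp)
        tn = total - tp - fn - fp
        se = _rate(tp, tp + fn, "sensitivity", names[c])
        sp = _rate(tn, tn + fp, "specificity", names[c])
        pr = _rate(tp, tp + fp, "precision", names[c])
        f1 = _rate(2 * pr * se, pr + se, "F1", names[c])
        report.per_class[names[c]] = {
            "sensitivity": se, "specificity": sp, "precision": pr,
            "f1": f1, "recall": se,
        }
        se_list.append(se); sp_list.append(sp); pr_list.append(pr); f1_list.append(f1)
    report.accuracy = float(np.trace(cm) / total)
    report.macro_sensitivity = float(np.mean(se_list))
    report.macro_specificity = float(np.mean(sp_list))
    report.macro_precision = float(np.mean(pr_list))
    report.macro_f1 = float(np.mean(f1_list))
    report.macro_recall = report.macro_sensitivity
    # micro F1 over one-vs-rest pools equals accuracy for single-label tasks
    report.micro_f1 = report.accuracy
    report.zero_division_flags = flags
    return report


TABLE_COLUMNS = ["Model", "Sensitivity (SE)", "Specificity (SP)", "Accuracy", "F1-Score"]


def comparison_table(named_reports) -> pd.DataFrame:
    """Model-comparison table: one row of macro metrics per (name, report)."""
    rows = []
    for name, rep in named_reports:
        rows.append({
            "Model": name,
            "Sensitivity (SE)": rep.macro_sensitivity,
            "Specificity (SP)": rep.macro_specificity,
            "Accuracy": rep.accuracy,
            "F1-Score": rep.macro_f1,
        })
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def save_confusion_png(report: EvalReport, path) -> None:
    """Render the confusion matrix as a PNG (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cm = np.asarray(report.confusion)
    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(cm, cmap="Blues")
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    ax.set_xticks(range(cm.shape[1]), report.class_names, rotation=45, ha="right")
    ax.set_yticks(range(cm.shape[0]), report.class_names)
    for i in range(cm.shape[0]):
        for j in range(cm.shape[1]):
            ax.text(j, i, str(cm[i, j]), ha="center", va="center",
                    color="white" if cm[i, j] > cm.max() / 2 else "black")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
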