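"""Decoder evaluation: confusion-matrix metrics, Cohen's kappa, and ITR.

Accuracy, per-class precision/recall/F1 (macro-averaged), and kappa are
derived from the confusion matrix. The information transfer rate converts
accuracy into communicated bits per minute:

    ITR = T * (log2 C + A log2 A + (1-A) log2((1-A)/(C-1)))

with T decisions per minute, C classes and accuracy A — the standard BCI
throughput measure, assuming errors spread evenly over the C-1 wrong
classes. A 4.5 s trial gives T = 60/4.5 = 13.33 decisions per minute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import TrialDataset

__all__ = [
    "MetricsBundle",
    "confusion_matrix",
    "classification_metrics",
    "kappa_from_accuracy",
    "itr_bits_per_min",
    "evaluate_subject",
]


@dataclass
class MetricsBundle:
    """All per-subject metrics derived from one evaluation run."""

    accuracy: float
    kappa: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    confusion: np.ndarray
    itr_bits_per_min: float | None = field(default=None)

    @property
    def macro_precision(self) -> float:
        return float(np.mean(self.precision))

    @property
    def macro_recall(self) -> float:
        return float(np.mean(self.recall))

    @property
    def macro_f1(self) -> float:
        return float(np.mean(self.f1))

    def to_dict(self) -> dict:
        d = {
            "accuracy_pct": 100.0 * self.accuracy,
            "kappa": self.kappa,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
        }
        for j, (p, r, f1) in enumerate(zip(self.precision, self.recall, self.f1)):
            d[f"precision_class{j + 1}"] = float(p)
            d[f"recall_class{j + 1}"] = float(r)
            d[f"f1_class{j + 1}"] = float(f1)
        if self.itr_bits_per_min is not None:
            d["itr_bits_per_min"] = self.itr_bits_per_min
        return d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.to_dict()])


def confusion_matrix(true_labels, predicted_labels, n_classes: int) -> np.ndarray:
    """Counts[i, j] = trials with true class i+1 predicted as class j+1."""
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_labels, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    for name, arr in (("true", t), ("predicted", p)):
        if arr.size and (arr.min() < 1 or arr.max() > n_classes):
            raise ValueError(f"{name} labels outside 1..{n_classes}")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (t - 1, p - 1), 1)
    return cm


def classification_metrics(cm: np.ndarray,
                           itr_decisions_per_min: float | None = None
                           ) -> MetricsBundle:
    """Accuracy, kappa and per-class precision/recall/F1 from a confusion matrix.

    Kappa uses the general chance-agreement formula
    ``p_e = sum_i row_i * col_i / N^2``. Empty rows or columns make the
    corresponding recall or precision undefined; they are reported as 0
    with a warning so macro averages stay defined for degenerate predictors.
    """
    cm = np.asarray(cm)
    total = cm.sum()
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    diag = np.diag(cm).astype(np.float64)
    row = cm.sum(axis=1).astype(np.float64)
    col = cm.sum(axis=0).astype(np.float64)
    if np.any(row == 0) or np.any(col == 0):
        warnings.warn("empty confusion-matrix row/column; affected "
                      "precision/recall reported as 0", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, diag / np.maximum(col, 1), 0.0)
        recall = np.where(row > 0, diag / np.maximum(row, 1), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.maximum(denom, 1e-300), 0.0)
    accuracy = float(diag.sum() / total)
    p_e = float((row * col).sum() / total ** 2)
    kappa = (accuracy - p_e) / (1.0 - p_e) if p_e < 1.0 else 1.0
    itr = None
    if itr_decisions_per_min is not None:
        itr = itr_bits_per_min(accuracy, cm.shape[0], itr_decisions_per_min)
    return MetricsBundle(accuracy=accuracy, kappa=float(kappa),
                         precision=precision, recall=recall, f1=f1,
                         confusion=cm, itr_bits_per_min=itr)


def kappa_from_accuracy(accuracy, n_classes: int):
    """Balanced-chance shortcut kappa = (A - 1/C) / (1 - 1/C).

    Equals the confusion-matrix kappa whenever the predicted marginals are
    uniform; published per-subject kappas for balanced four-class motor
    imagery follow this identity.
    """
    a = np.asarray(accuracy, dtype=np.float64)
    if np.any(a < 0) or np.any(a > 1):
        raise ValueError("accuracy must lie in [0, 1]")
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    chance = 1.0 / n_classes
    out = (a - chance) / (1.0 - chance)
    return float(out) if np.isscalar(accuracy) else out


def itr_bits_per_min(accuracy, n_classes: int, decisions_per_min: float):
    """Information transfer rate in bits/min (vectorized over accuracy).

    Zero at chance level (A = 1/C); ``T log2 C`` at perfect accuracy; the
    ``x log2 x`` terms take their limiting value 0 at A in {0, 1}.
    """
    a = np.asarray(accuracy, dtype=np.float64)
    if np.any(a < 0) or np.any(a > 1):
        raise ValueError("accuracy must lie in [0, 1]")
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if decisions_per_min <= 0:
        raise ValueError("decisions_per_min must be positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(a > 0, a * np.log2(np.maximum(a, 1e-300)), 0.0)
        t2 = np.where(a < 1, (1 - a) * np.log2(
            np.maximum((1 - a) / (n_classes - 1), 1e-300)), 0.0)
    bits = np.log2(n_classes) + t1 + t2
    out = decisions_per_min * bits
    return float(out) if np.isscalar(accuracy) else out


def evaluate_subject(model, test_data: TrialDataset,
                     trial_duration_s: float = 4.5) -> MetricsBundle:
    """Evaluation-mode forward pass + argmax decisions + all metrics.

    ITR is computed at ``60 / trial_duration_s`` decisions per minute.
    Argmax ties resolve to the lowest class index.
    """
    if test_data.n_channels != model.spec.channels \
            or test_data.n_samples != model.spec.time_samples:
        raise ValueError(
            f"test data ({test_data.n_channels} x {test_data.n_samples}) does "
            f"not match model ({model.spec.channels} x {model.spec.time_samples})"
        )
    pred = model.predict_labels(test_data.signals)
    cm = confusion_matrix(test_data.labels, pred, test_data.n_classes)
    return classification_metrics(cm, itr_decisions_per_min=60.0 / trial_duration_s)
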