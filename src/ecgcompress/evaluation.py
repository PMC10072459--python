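"""Evaluation: confusion matrices, the per-class/macro metric set, ROC and PR
curves, and the CR × method benchmark grid.

Metrics are computed one-vs-rest per class from the confusion matrix:

    Accuracy    = (TP + TN) / (TP + TN + FP + FN)      (overall: trace / total)
    Precision   = TP / (TP + FP)
    Sensitivity = TP / (TP + FN)
    F1          = 2 · Precision · Sensitivity / (Precision + Sensitivity)
    Score       = (mean F1)²

Macro values are unweighted means over classes; zero-denominator cells return
0 with a logged warning (they arise only on degenerate tiny test sets).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (
    auc,
    average_precision_score,
    confusion_matrix as _sk_confusion,
    precision_recall_curve,
    roc_curve,
)

from .classifier import ClassifierConfig, build_classifier_plan
from .compression import (
    CompressionConfig,
    build_compressor_plan,
    pca_fit,
    pca_transform,
    svd_fit,
    svd_transform,
)
from .io import BeatDataset
from .preprocessing import SplitConfig, split_train_test
from .training import TrainConfig, TrainedModel, train

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationReport",
    "confusion_matrix",
    "metrics_from_confusion",
    "evaluate_model",
    "roc_pr_curves",
    "BenchmarkResult",
    "run_benchmark",
]


def confusion_matrix(true_labels, predicted_labels, class_names) -> np.ndarray:
    """Count matrix with rows = true class, columns = predicted class."""
    true_labels = np.asarray([str(x) for x in true_labels])
    predicted_labels = np.asarray([str(x) for x in predicted_labels])
    if true_labels.shape != predicted_labels.shape:
        raise ValueError("label vectors must have equal length")
    class_names = [str(c) for c in class_names]
    known = set(class_names)
    for label in np.concatenate([true_labels, predicted_labels]):
        if label not in known:
            raise ValueError(f"label {label!r} not in class_names {class_names}")
    return _sk_confusion(true_labels, predicted_labels, labels=class_names)


@dataclass
class EvaluationReport:
    """Confusion matrix plus per-class and macro metrics."""

    class_names: list[str]
    confusion: np.ndarray
    per_class: pd.DataFrame
    accuracy: float
    macro_precision: float
    macro_sensitivity: float
    macro_f1: float
    score: float
    curves: dict = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        return {
            "class_names": self.class_names,
            "confusion": self.confusion.tolist(),
            "per_class": self.per_class.to_dict(orient="index"),
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_sensitivity": self.macro_sensitivity,
            "macro_f1": self.macro_f1,
            "score": self.score,
        }

    def summary(self) -> str:
        lines = ["Confusion matrix (rows = true, columns = predicted):"]
        header = "      " + "".join(f"{c:>8}" for c in self.class_names)
        lines.append(header)
        for name, row in zip(self.class_names, self.confusion):
            lines.append(f"{name:>6}" + "".join(f"{int(v):>8}" for v in row))
        lines.append("")
        lines.append(self.per_class.round(4).to_string())
        lines.append("")
        lines.append(
            f"Accuracy {self.accuracy:.4f}  macro Precision {self.macro_precision:.4f}  "
            f"macro Sensitivity {self.macro_sensitivity:.4f}  macro F1 {self.macro_f1:.4f}  "
            f"Score {self.score:.4f}"
        )
        return "\n".join(lines)


def _safe_div(numer: float, denom: float, what: str) -> float:
    if denom == 0:
        logger.warning("%s undefined (zero denominator); reporting 0", what)
        return 0.0
    return numer / denom


def metrics_from_confusion(
    confusion: np.ndarray, class_names: list[str] | None = None
) -> EvaluationReport:
    """Per-class precision/sensitivity/F1 and macro metrics from a confusion
    count matrix."""
    confusion = np.asarray(confusion)
    if confusion.ndim != 2 or confusion.shape[0] != confusion.shape[1]:
        raise ValueError("confusion matrix must be square")
    total = confusion.sum()
    if total == 0:
        raise ValueError("confusion matrix is all zeros")
    if class_names is None:
        class_names = [str(i) for i in range(confusion.shape[0])]
    tp = np.diag(confusion).astype(float)
    fp = confusion.sum(axis=0) - tp
    fn = confusion.sum(axis=1) - tp
    rows = {}
    for i, name in enumerate(class_names):
        precision = _safe_div(tp[i], tp[i] + fp[i], f"precision[{name}]")
        sensitivity = _safe_div(tp[i], tp[i] + fn[i], f"sensitivity[{name}]")
        f1 = _safe_div(2 * precision * sensitivity, precision + sensitivity, f"F1[{name}]")
        rows[name] = {"precision": precision, "sensitivity": sensitivity, "f1": f1}
    per_class = pd.DataFrame.from_dict(rows, orient="index")
    macro_f1 = float(per_class["f1"].mean())
    return EvaluationReport(
        class_names=list(class_names),
        confusion=confusion,
        per_class=per_class,
        accuracy=float(np.trace(confusion) / total),
        macro_precision=float(per_class["precision"].mean()),
        macro_sensitivity=float(per_class["sensitivity"].mean()),
        macro_f1=macro_f1,
        score=macro_f1**2,
    )


def roc_pr_curves(probabilities: np.ndarray, true_labels, class_names) -> dict:
    """One-vs-rest ROC and precision-recall curves with areas, per class.

    Classes with single-valued truth (no positives or no negatives in the
    evaluated set) have undefined curves and are skipped with a note.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    true_labels = np.asarray([str(x) for x in true_labels])
    curves = {}
    for i, name in enumerate(class_names):
        positive = (true_labels == str(name)).astype(int)
        if positive.min() == positive.max():
            logger.info("class %s: single-class truth, ROC/PR skipped", name)
            continue
        fpr, tpr, _ = roc_curve(positive, probabilities[:, i])
        precision, recall, _ = precision_recall_curve(positive, probabilities[:, i])
        curves[str(name)] = {
            "fpr": fpr,
            "tpr": tpr,
            "roc_auc": float(auc(fpr, tpr)),
            "precision": precision,
            "recall": recall,
            "average_precision": float(average_precision_score(positive, probabilities[:, i])),
        }
    return curves


def evaluate_model(
    model: TrainedModel, test_set: BeatDataset, with_curves: bool = False
) -> EvaluationReport:
    """Predict the test set and compile the full metric report."""
    predicted = model.predict(test_set.beats)
    matrix = confusion_matrix(test_set.labels, predicted, test_set.class_names)
    report = metrics_from_confusion(matrix, list(test_set.class_names))
    if with_curves:
        probs = model.predict_proba(test_set.beats)
        report.curves = roc_pr_curves(probs, test_set.labels, test_set.class_names)
    return report


# ---------------------------------------------------------------------------
# Benchmark grid
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkResult:
    """Accuracy table (rows = CR, columns = method/variant) plus the per-cell
    seeds that make each cell independently reproducible."""

    accuracy: pd.DataFrame
    seeds: pd.DataFrame

    def to_csv(self, path: str) -> None:
        self.accuracy.to_csv(path, index_label="cr")


def _cell_name(method: str, variant: str) -> str:
    return method if variant == "full" else f"{method}:{variant}"


def run_benchmark(
    dataset: BeatDataset,
    crs=(0.5, 0.2, 0.05),
    methods=("cnn", "svd", "pca"),
    variants=("full",),
    train_config: TrainConfig = TrainConfig(),
    split_config: SplitConfig = SplitConfig(),
) -> BenchmarkResult:
    """Sweep compression ratios × compression methods × classifier variants.

    Each grid cell trains from scratch on the same train/test partition:
    ``cnn`` trains compressor+classifier jointly; ``svd``/``pca`` fit their
    basis on the training beats only, then train the classifier on the
    projected data.  A failing cell is logged and reported as NaN.
    """
    train_set, test_set = split_train_test(dataset, split_config)
    n = dataset.beat_length
    n_classes = len(dataset.class_names)
    acc_rows, seed_rows = {}, {}
    for row, cr in enumerate(crs):
        comp_cfg = CompressionConfig(n=n, cr=cr)
        acc_rows[cr], seed_rows[cr] = {}, {}
        for col, (method, variant) in enumerate(
            [(m, v) for m in methods for v in variants]
        ):
            cell = _cell_name(method, variant)
            cell_seed = train_config.seed + 1000 * row + 10 * col
            cell_cfg = TrainConfig(
                epochs=train_config.epochs,
                batch_size=train_config.batch_size,
                initial_lr=train_config.initial_lr,
                lr_factor=train_config.lr_factor,
                lr_patience=train_config.lr_patience,
                min_lr=train_config.min_lr,
                min_delta=train_config.min_delta,
                validation_fraction=train_config.validation_fraction,
                seed=cell_seed,
            )
            seed_rows[cr][cell] = cell_seed
            try:
                cls_plan = build_classifier_plan(
                    ClassifierConfig(k=comp_cfg.k, n_classes=n_classes, variant=variant)
                )
                if method == "cnn":
                    comp_plan = build_compressor_plan(comp_cfg)
                    model = train(comp_plan, cls_plan, train_set, cell_cfg)
                    x_test = test_set.beats
                else:
                    if method == "svd":
                        basis = svd_fit(train_set.beats, comp_cfg.k)
                        z_train = svd_transform(basis, train_set.beats)
                        x_test = svd_transform(basis, test_set.beats)
                    elif method == "pca":
                        basis = pca_fit(train_set.beats, comp_cfg.k)
                        z_train = pca_transform(basis, train_set.beats)
                        x_test = pca_transform(basis, test_set.beats)
                    else:
                        raise ValueError(f"unknown compression method {method!r}")
                    compressed_train = BeatDataset(
                        z_train, train_set.labels, comp_cfg.k, list(train_set.class_names)
                    )
                    model = train(None, cls_plan, compressed_train, cell_cfg)
                predicted = model.predict(x_test)
                matrix = confusion_matrix(test_set.labels, predicted, test_set.class_names)
                acc_rows[cr][cell] = float(np.trace(matrix) / matrix.sum())
            except Exception:
                logger.exception("benchmark cell (cr=%g, %s) failed; skipping", cr, cell)
                acc_rows[cr][cell] = np.nan
    accuracy = pd.DataFrame.from_dict(acc_rows, orient="index")
    seeds = pd.DataFrame.from_dict(seed_rows, orient="index")
    return BenchmarkResult(accuracy, seeds)
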