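"""High-level modelling surface: a model object built from a beat dataset
whose ``fit()`` returns a results object with estimates, diagnostics and a
summary table — the familiar fit/results idiom of statistical modelling
packages.

Example
-------
>>> from ecgcompress import SyntheticBeatSpec, generate_dataset
>>> from ecgcompress.model import CompressedBeatClassifier
>>> data = generate_dataset(SyntheticBeatSpec(seed=0), n_per_class=250)
>>> res = CompressedBeatClassifier(data, cr=0.2).fit(epochs=50)
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classifier import ClassifierConfig, build_classifier_plan
from .compression import (
    CompressionConfig,
    build_compressor_plan,
    pca_fit,
    pca_transform,
    svd_fit,
    svd_transform,
)
from .evaluation import EvaluationReport, confusion_matrix, evaluate_model, metrics_from_confusion
from .io import BeatDataset
from .preprocessing import SplitConfig, split_train_test
from .training import TrainConfig, TrainedModel, train

__all__ = ["CompressedBeatClassifier", "BeatClassificationResults"]


class CompressedBeatClassifier:
    """Compressed-domain beat classifier specification bound to a dataset.

    Parameters
    ----------
    dataset
        Labelled fixed-length beats (already normalized to [0, 1]).
    cr
        Compression ratio ``k / n`` in (0, 1].
    compression
        ``"cnn"`` for the learned convolutional compressor (trained jointly
        with the classifier), or ``"svd"`` / ``"pca"`` for the classical
        projection baselines.
    variant
        Classifier architecture: ``"full"`` (parallel-branch front end),
        ``"no_parallel"``, ``"plus_lstm"`` or ``"plus_bilstm"``.
    split
        Train/test partition configuration (0.8/0.2, seed 0 by default).
    """

    def __init__(
        self,
        dataset: BeatDataset,
        cr: float = 0.2,
        compression: str = "cnn",
        variant: str = "full",
        split: SplitConfig = SplitConfig(),
    ) -> None:
        if compression not in ("cnn", "svd", "pca"):
            raise ValueError(f"compression must be cnn/svd/pca, got {compression!r}")
        self.dataset = dataset
        self.compression = compression
        self.compression_config = CompressionConfig(n=dataset.beat_length, cr=cr)
        self.classifier_config = ClassifierConfig(
            k=self.compression_config.k,
            n_classes=len(dataset.class_names),
            variant=variant,
        )
        self.split = split
        self.train_set, self.test_set = split_train_test(dataset, split)

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, label_column: str | None = None, **kwargs
    ) -> "CompressedBeatClassifier":
        """Build from a DataFrame of one beat per row, label in
        ``label_column`` (default: the last column)."""
        if label_column is None:
            label_column = frame.columns[-1]
        labels = frame[label_column].astype(str).to_numpy()
        beats = frame.drop(columns=[label_column]).to_numpy(dtype=float)
        dataset = BeatDataset(
            beats, labels, beats.shape[1], sorted(set(labels.tolist()))
        )
        return cls(dataset, **kwargs)

    def fit(
        self, epochs: int = 50, seed: int = 0, **train_kwargs
    ) -> "BeatClassificationResults":
        """Train on the 0.8 split and evaluate on the held-out 0.2 split."""
        config = TrainConfig(epochs=epochs, seed=seed, **train_kwargs)
        cls_plan = build_classifier_plan(self.classifier_config)
        if self.compression == "cnn":
            comp_plan = build_compressor_plan(self.compression_config)
            fitted = train(comp_plan, cls_plan, self.train_set, config)
            report = evaluate_model(fitted, self.test_set, with_curves=True)
            basis = None
        else:
            k = self.compression_config.k
            if self.compression == "svd":
                basis = svd_fit(self.train_set.beats, k)
                z_train = svd_transform(basis, self.train_set.beats)
                z_test = svd_transform(basis, self.test_set.beats)
            else:
                basis = pca_fit(self.train_set.beats, k)
                z_train = pca_transform(basis, self.train_set.beats)
                z_test = pca_transform(basis, self.test_set.beats)
            compressed_train = BeatDataset(
                z_train, self.train_set.labels, k, list(self.train_set.class_names)
            )
            fitted = train(None, cls_plan, compressed_train, config)
            predicted = fitted.predict(z_test)
            matrix = confusion_matrix(
                self.test_set.labels, predicted, self.test_set.class_names
            )
            report = metrics_from_confusion(matrix, list(self.test_set.class_names))
        return BeatClassificationResults(self, fitted, report, basis)


class BeatClassificationResults:
    """Fitted compressed-domain classifier: weights, training history, and
    held-out evaluation."""

    def __init__(
        self,
        model: CompressedBeatClassifier,
        fitted: TrainedModel,
        report: EvaluationReport,
        basis=None,
    ) -> None:
        self.model = model
        self.fitted = fitted
        self.report = report
        self.basis = basis

    # -- delegated quantities -------------------------------------------
    @property
    def history(self) -> pd.DataFrame:
        return self.fitted.history

    @property
    def accuracy(self) -> float:
        return self.report.accuracy

    @property
    def confusion(self) -> np.ndarray:
        return self.report.confusion

    def predict(self, beats: np.ndarray) -> np.ndarray:
        if self.model.compression == "svd":
            beats = svd_transform(self.basis, beats)
        elif self.model.compression == "pca":
            beats = pca_transform(self.basis, beats)
        return self.fitted.predict(np.asarray(beats, dtype=float))

    def predict_proba(self, beats: np.ndarray) -> np.ndarray:
        if self.model.compression == "svd":
            beats = svd_transform(self.basis, beats)
        elif self.model.compression == "pca":
            beats = pca_transform(self.basis, beats)
        return self.fitted.predict_proba(np.asarray(beats, dtype=float))

    def summary(self) -> str:
        cc = self.model.compression_config
        head = [
            "Compressed-Domain Beat Classification Results",
            "=" * 61,
            f"Compression:        {self.model.compression}  (CR={cc.cr:g}, n={cc.n} -> k={cc.k})",
            f"Classifier variant: {self.model.classifier_config.variant}",
            f"Beats:              {len(self.model.train_set)} train / {len(self.model.test_set)} test",
            f"Epochs run:         {len(self.history)}   final lr: {self.history['lr'].iloc[-1]:g}"
            if len(self.history)
            else "Epochs run:         0",
            "=" * 61,
        ]
        return "\n".join(head) + "\n" + self.report.summary()

    # -- plotting --------------------------------------------------------
    def plot_history(self, ax=None):
        """Training/validation loss and accuracy per epoch."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        h = self.history
        ax.plot(h["epoch"], h["loss"], label="train loss")
        ax.plot(h["epoch"], h["val_loss"], label="val loss")
        ax.set_xlabel("epoch")
        ax.set_ylabel("cross-entropy loss")
        twin = ax.twinx()
        twin.plot(h["epoch"], h["accuracy"], "--", label="train acc")
        twin.plot(h["epoch"], h["val_accuracy"], "--", label="val acc")
        twin.set_ylabel("accuracy")
        ax.legend(loc="upper right")
        return ax

    def plot_confusion(self, ax=None):
        """Heat-map rendering of the held-out confusion matrix."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        names = self.report.class_names
        ax.imshow(self.confusion, cmap="Blues")
        ax.set_xticks(range(len(names)), names)
        ax.set_yticks(range(len(names)), names)
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        for i in range(len(names)):
            for j in range(len(names)):
                ax.text(j, i, str(int(self.confusion[i, j])), ha="center", va="center")
        return ax
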