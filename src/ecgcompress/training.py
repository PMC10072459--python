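"""End-to-end training of the compressor + classifier pair.

The pair is optimized jointly on the multi-class cross-entropy

    L = -(1/N) Σ_i Σ_c y_ic · log(p_ic)

with Adam (initial learning rate 0.001), minibatches of 64 and 50 epochs by
default.  There is no reconstruction objective: the compressor's only training
signal is the classification loss flowing back through the classifier, which
is what makes the learned compression discriminative rather than generic.

The learning rate follows a reduce-on-plateau schedule (factor 0.8, patience
5 epochs, floor 1e-5) driven by the loss on an internal validation split cut
from the training set (10%, seeded).  The whole procedure is a pure function
of the data and the configured seed: parameter initialization, batch
shuffling, dropout masks and the validation split all draw from one seeded
generator, so repeated runs reproduce histories exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import BeatDataset
from .nn import Adam, Network, NetworkPlan

__all__ = ["TrainConfig", "TrainedModel", "cross_entropy", "one_hot", "train"]

_EPS = 1e-7


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol parameters.

    All defaults are the pipeline's standard protocol: 50 epochs, batch 64,
    Adam at 0.001 with reduce-on-plateau (×0.8 after 5 non-improving epochs,
    floored at 1e-5) on the internal validation loss.
    """

    epochs: int = 50
    batch_size: int = 64
    initial_lr: float = 1e-3
    lr_factor: float = 0.8
    lr_patience: int = 5
    min_lr: float = 1e-5
    min_delta: float = 1e-4
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if not 0.0 < self.initial_lr:
            raise ValueError("initial_lr must be positive")
        if not 0.0 < self.lr_factor <= 1.0:
            raise ValueError("lr_factor must be in (0, 1]")
        if not 0.0 <= self.validation_fraction < 0.5:
            raise ValueError("validation_fraction must be in [0, 0.5)")


def one_hot(indices: np.ndarray, n_classes: int) -> np.ndarray:
    eye = np.eye(n_classes)
    return eye[np.asarray(indices, dtype=int)]


def cross_entropy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean negative log-likelihood of one-hot truths under predicted
    probabilities.

    Probabilities at a true class are clipped below at 1e-7 before the log, so
    a confidently wrong prediction yields a large finite loss rather than an
    infinity.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"shape mismatch: {y_true.shape} vs {y_pred.shape}")
    p = np.clip(y_pred, _EPS, 1.0)
    return float(-(y_true * np.log(p)).sum() / len(y_true))


@dataclass
class TrainedModel:
    """A fitted compressor+classifier pair with its training history.

    ``compressor`` is ``None`` when the classifier was trained on externally
    compressed inputs (the SVD/PCA baselines).  ``history`` has one row per
    epoch: train/validation loss and accuracy plus the learning rate in force.
    """

    compressor: Network | None
    classifier: Network
    class_names: list[str]
    config: TrainConfig
    history: pd.DataFrame = field(default_factory=pd.DataFrame)

    def compress(self, beats: np.ndarray) -> np.ndarray:
        matrix = np.asarray(beats, dtype=float)
        if self.compressor is None:
            return matrix
        return self.compressor.forward(matrix[:, :, None], training=False)

    def predict_proba(self, beats: np.ndarray) -> np.ndarray:
        compressed = self.compress(beats)
        return self.classifier.forward(compressed[:, :, None], training=False)

    def predict(self, beats: np.ndarray) -> np.ndarray:
        probs = self.predict_proba(beats)
        names = list(self.class_names)
        while len(names) < probs.shape[1]:  # head wider than the label set
            names.append(f"class{len(names)}")
        return np.asarray(names)[probs.argmax(axis=1)]

    # -- checkpointing ---------------------------------------------------
    def save(self, run_dir: str) -> None:
        """Write weights (.npz), a JSON sidecar (plans + config + classes)
        and the per-epoch history CSV into ``run_dir``."""
        import dataclasses
        import json
        import os

        os.makedirs(run_dir, exist_ok=True)

        def dump_net(net: Network, name: str) -> None:
            arrays = {}
            for i, entry in enumerate(net.get_weights()):
                for key, value in entry.items():
                    arrays[f"{i}:{key}"] = value
            np.savez(os.path.join(run_dir, name + ".npz"), **arrays)

        if self.compressor is not None:
            dump_net(self.compressor, "compressor")
        dump_net(self.classifier, "classifier")
        sidecar = {
            "class_names": self.class_names,
            "config": dataclasses.asdict(self.config),
            "compressor_plan": self.compressor.plan.to_dicts() if self.compressor else None,
            "classifier_plan": self.classifier.plan.to_dicts(),
        }
        with open(os.path.join(run_dir, "model.json"), "w") as fh:
            json.dump(sidecar, fh, indent=2)
        self.history.to_csv(os.path.join(run_dir, "history.csv"), index=False)

    @classmethod
    def load(cls, run_dir: str) -> "TrainedModel":
        import json
        import os

        with open(os.path.join(run_dir, "model.json")) as fh:
            sidecar = json.load(fh)
        rng = np.random.default_rng(0)

        def load_net(plan_dicts, name: str) -> Network:
            plan = NetworkPlan.from_dicts(plan_dicts)
            net = Network(plan, rng)
            with np.load(os.path.join(run_dir, name + ".npz")) as data:
                weights = [dict() for _ in plan]
                for key in data.files:
                    idx, pname = key.split(":", 1)
                    weights[int(idx)][pname] = data[key]
            net.set_weights(weights)
            return net

        compressor = (
            load_net(sidecar["compressor_plan"], "compressor")
            if sidecar["compressor_plan"]
            else None
        )
        classifier = load_net(sidecar["classifier_plan"], "classifier")
        config = TrainConfig(**sidecar["config"])
        history_path = os.path.join(run_dir, "history.csv")
        history = pd.read_csv(history_path) if os.path.exists(history_path) else pd.DataFrame()
        return cls(compressor, classifier, sidecar["class_names"], config, history)


def _forward_backward(
    compressor: Network | None,
    classifier: Network,
    x: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
) -> tuple[float, np.ndarray]:
    """One training step's forward pass, loss and backward pass."""
    if compressor is not None:
        compressed = compressor.forward(x[:, :, None], training=True, rng=rng)
    else:
        compressed = x
    probs = classifier.forward(compressed[:, :, None], training=True, rng=rng)
    loss = cross_entropy(y, probs)
    # dL/dp for the mean NLL; the softmax output layer applies its Jacobian
    dprobs = -(y / np.clip(probs, _EPS, 1.0)) / len(x)
    dcompressed = classifier.backward(dprobs)
    if compressor is not None:
        compressor.backward(dcompressed[:, :, 0])
    return loss, probs


def _evaluate(
    compressor: Network | None, classifier: Network, x: np.ndarray, y: np.ndarray
) -> tuple[float, float]:
    if compressor is not None:
        compressed = compressor.forward(x[:, :, None], training=False)
    else:
        compressed = x
    probs = classifier.forward(compressed[:, :, None], training=False)
    loss = cross_entropy(y, probs)
    acc = float((probs.argmax(axis=1) == y.argmax(axis=1)).mean())
    return loss, acc


def train(
    compressor_plan: NetworkPlan | None,
    classifier_plan: NetworkPlan,
    train_set: BeatDataset,
    config: TrainConfig = TrainConfig(),
) -> TrainedModel:
    """Fit the (compressor, classifier) pair on a labelled beat dataset.

    ``compressor_plan`` may be ``None`` to train the classifier alone on
    already-compressed beats (the classical-baseline route).  Plans must
    chain: dataset beat length → compressor input, compressor output →
    classifier input, classifier output ≥ number of label classes.
    """
    n_classes = classifier_plan.output_shape[0]
    class_names = list(train_set.class_names)
    if len(class_names) > n_classes:
        raise ValueError(
            f"dataset has {len(class_names)} classes but the classifier outputs {n_classes}"
        )
    first_plan = compressor_plan if compressor_plan is not None else classifier_plan
    if first_plan.input_shape[0] != train_set.beat_length:
        raise ValueError(
            f"input length {first_plan.input_shape[0]} does not match beat length "
            f"{train_set.beat_length}"
        )
    if compressor_plan is not None and compressor_plan.output_shape[0] != classifier_plan.input_shape[0]:
        raise ValueError("compressor output length does not match classifier input length")

    rng = np.random.default_rng(config.seed)
    compressor = Network(compressor_plan, rng) if compressor_plan is not None else None
    classifier = Network(classifier_plan, rng)

    x_all = train_set.beats
    y_all = one_hot(train_set.label_indices(), n_classes)
    n = len(x_all)
    n_val = int(round(config.validation_fraction * n))
    perm = rng.permutation(n)
    val_idx, fit_idx = perm[:n_val], perm[n_val:]
    x_fit, y_fit = x_all[fit_idx], y_all[fit_idx]
    x_val, y_val = x_all[val_idx], y_all[val_idx]

    pairs = classifier.parameters() + (compressor.parameters() if compressor else [])
    optimizer = Adam(pairs, lr=config.initial_lr)

    best_val = np.inf
    wait = 0
    records = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(x_fit))
        losses, correct, seen = [], 0, 0
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            if compressor is not None:
                compressor.zero_grads()
            classifier.zero_grads()
            loss, probs = _forward_backward(compressor, classifier, x_fit[batch], y_fit[batch], rng)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch + 1}, batch {start // config.batch_size}, "
                    f"lr {optimizer.lr:g}"
                )
            optimizer.step()
            losses.append(loss)
            correct += int((probs.argmax(axis=1) == y_fit[batch].argmax(axis=1)).sum())
            seen += len(batch)
        if len(x_val):
            val_loss, val_acc = _evaluate(compressor, classifier, x_val, y_val)
        else:
            val_loss, val_acc = float(np.mean(losses)), correct / max(seen, 1)
        records.append(
            {
                "epoch": epoch + 1,
                "loss": float(np.mean(losses)),
                "accuracy": correct / max(seen, 1),
                "val_loss": val_loss,
                "val_accuracy": val_acc,
                "lr": optimizer.lr,
            }
        )
        # reduce-on-plateau on validation loss
        if val_loss < best_val - config.min_delta:
            best_val = val_loss
            wait = 0
        else:
            wait += 1
            if wait >= config.lr_patience:
                optimizer.lr = max(optimizer.lr * config.lr_factor, config.min_lr)
                wait = 0

    history = pd.DataFrame.from_records(records)
    return TrainedModel(compressor, classifier, class_names, config, history)
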