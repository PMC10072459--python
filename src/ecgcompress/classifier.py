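"""Classification network plans: the parallel-branch CNN and its ablation
variants.

The full classifier takes a compressed beat of length ``k`` and processes it
through two parallel convolution branches whose outputs are fused along the
time axis, then through three convolutional blocks and a softmax head:

    input(k×1) ─┬─ conv1d(16,3)+BN+pool(2) ─┐
                └─ conv1d(16,3)+BN+pool(2) ─┴─ concat(time) →
    conv1d(16,3) → conv1d(16,3) → pool(2) → dropout(0.5) →
    conv1d(64,3) → conv1d(64,3) → pool(3) → dropout(0.5) →
    conv1d(64,3) → conv1d(64,3) → pool(4) → dropout(0.5) →
    flatten → dense(n_classes, softmax)

The two half-length branch outputs concatenate back to a k-long, 16-channel
sequence, so the trunk sees the compressed length regardless of k.  At k=52
the trunk shape chain is 52→26→8→2 and the head flattens 2×64=128 features
into a 516-parameter dense layer.

Variants (ablations):

* ``no_parallel`` — the parallel front end is removed; the trunk's three
  convolution blocks consume the input directly.
* ``plus_lstm`` / ``plus_bilstm`` — a 64-unit (Bi)LSTM returning its hidden
  sequence is inserted after the third convolution block, before the flatten.

For small k the fixed pool sizes (2, 3, 4) can exceed the remaining sequence
length; each pool is then clamped to the current length (and the clamping
logged), which keeps the whole CR sweep down to 0.05 runnable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Network, NetworkPlan, PlanBuilder

__all__ = ["VARIANTS", "ClassifierConfig", "build_classifier_plan", "classify_forward"]

VARIANTS = ("full", "no_parallel", "plus_lstm", "plus_bilstm")


@dataclass(frozen=True)
class ClassifierConfig:
    """Classifier architecture parameters.

    ``k`` is the compressed input length; ``dropout_rate`` applies after each
    trunk pooling stage; ``lstm_units`` sizes the recurrent ablation layers
    (64, matching the trunk width).
    """

    k: int
    n_classes: int = 4
    variant: str = "full"
    dropout_rate: float = 0.5
    lstm_units: int = 64

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


def build_classifier_plan(config: ClassifierConfig) -> NetworkPlan:
    """Build the classification-network plan for ``config``."""
    b = PlanBuilder()
    inp = b.input(config.k, 1, name="compressed_beat")

    if config.variant == "no_parallel":
        trunk_in = inp
    else:
        branches = []
        for side in ("a", "b"):
            conv = b.conv1d(16, 3, after=inp, name=f"branch_{side}_conv")
            bn = b.batchnorm(after=conv, name=f"branch_{side}_bn")
            branches.append(b.maxpool(2, after=bn, name=f"branch_{side}_pool"))
        trunk_in = b.concatenate((branches[0], branches[1]), name="fuse")

    # block 1: two 16-filter convolutions
    b.conv1d(16, 3, after=trunk_in, name="block1_conv1")
    b.conv1d(16, 3, name="block1_conv2")
    b.maxpool(2, name="block1_pool")
    b.dropout(config.dropout_rate, name="block1_dropout")
    # block 2: two 64-filter convolutions
    b.conv1d(64, 3, name="block2_conv1")
    b.conv1d(64, 3, name="block2_conv2")
    b.maxpool(3, name="block2_pool")
    b.dropout(config.dropout_rate, name="block2_dropout")
    # block 3: two 64-filter convolutions
    b.conv1d(64, 3, name="block3_conv1")
    b.conv1d(64, 3, name="block3_conv2")
    b.maxpool(4, name="block3_pool")
    last = b.dropout(config.dropout_rate, name="block3_dropout")

    if config.variant == "plus_lstm":
        last = b.lstm(config.lstm_units, after=last, name="lstm")
    elif config.variant == "plus_bilstm":
        last = b.lstm(config.lstm_units, bidirectional=True, after=last, name="bilstm")

    b.flatten(after=last, name="flatten")
    b.dense(config.n_classes, activation="softmax", name="class_probabilities")
    return b.build()


def classify_forward(model: Network, compressed: np.ndarray) -> np.ndarray:
    """Run the classifier in inference mode (dropout off, batchnorm on its
    moving statistics) over compressed beats, returning class probabilities.

    Each output row is non-negative and sums to 1.
    """
    compressed = np.asarray(compressed, dtype=float)
    expected = model.plan.input_shape[0]
    if compressed.ndim != 2 or compressed.shape[1] != expected:
        raise ValueError(
            f"classifier expects compressed beats of length {expected}, "
            f"got shape {compressed.shape}"
        )
    return model.forward(compressed[:, :, None], training=False)
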