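"""Compile a declarative :class:`~ecgcompress.nn.plan.NetworkPlan` into
runnable layers and execute forward/backward over the DAG."""

from __future__ import annotations

import numpy as np

from .layers import (
    BatchNorm,
    BiLSTM,
    Concatenate,
    Conv1D,
    Dense,
    Dropout,
    Flatten,
    InputLayer,
    Layer,
    LSTM,
    MaxPool1D,
)
from .plan import NetworkPlan


class Network:
    """A runnable network instantiated from a plan.

    ``forward`` runs layers in plan order (plans are topologically sorted by
    construction); ``backward`` accumulates output-gradients in reverse order
    and returns the gradient with respect to the network input, so networks
    can be chained (compressor -> classifier) with gradients flowing through.
    """

    def __init__(self, plan: NetworkPlan, rng: np.random.Generator) -> None:
        plan.validate()
        self.plan = plan
        self.layers: list[Layer] = []
        for i, spec in enumerate(plan):
            in_shape = plan[spec.inputs[0]].output_shape if spec.inputs else None
            if spec.kind == "input":
                layer: Layer = InputLayer()
            elif spec.kind == "conv1d":
                layer = Conv1D(in_shape[1], spec.filters, spec.kernel, spec.activation, rng)
            elif spec.kind == "maxpool1d":
                layer = MaxPool1D(spec.effective_pool or spec.pool)
            elif spec.kind == "batchnorm":
                layer = BatchNorm(in_shape[1])
            elif spec.kind == "concatenate":
                layer = Concatenate()
            elif spec.kind == "dropout":
                layer = Dropout(spec.rate)
            elif spec.kind == "flatten":
                layer = Flatten()
            elif spec.kind == "dense":
                layer = Dense(in_shape[0], spec.units, spec.activation, rng)
            elif spec.kind == "lstm":
                layer = LSTM(in_shape[1], spec.units, rng)
            elif spec.kind == "bilstm":
                layer = BiLSTM(in_shape[1], spec.units, rng)
            else:  # pragma: no cover - plan.validate rejects unknown kinds
                raise ValueError(f"unknown layer kind {spec.kind!r}")
            self.layers.append(layer)

    # -- execution -------------------------------------------------------
    def forward(
        self, x: np.ndarray, training: bool = False, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        if rng is None:
            rng = np.random.default_rng()
        outputs: list[np.ndarray] = []
        for spec, layer in zip(self.plan, self.layers):
            xs = [outputs[j] for j in spec.inputs] if spec.inputs else [x]
            outputs.append(layer.forward(xs, training, rng))
        self._n_layers = len(outputs)
        return outputs[-1]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        douts: list[np.ndarray | None] = [None] * self._n_layers
        douts[-1] = dy
        dx_input = None
        for i in range(self._n_layers - 1, -1, -1):
            if douts[i] is None:
                continue
            spec, layer = self.plan[i], self.layers[i]
            dxs = layer.backward(douts[i])
            if not spec.inputs:
                dx_input = dxs[0] if dx_input is None else dx_input + dxs[0]
                continue
            for j, dx in zip(spec.inputs, dxs):
                douts[j] = dx if douts[j] is None else douts[j] + dx
        return dx_input

    # -- parameters ------------------------------------------------------
    def zero_grads(self) -> None:
        for layer in self.layers:
            layer.zero_grads()

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(param, grad) pairs, aliased so in-place updates propagate."""
        pairs = []
        for layer in self.layers:
            for key in layer.params:
                pairs.append((layer.params[key], layer.grads[key]))
        return pairs

    def count_parameters(self) -> int:
        """Brute-force count of instantiated trainable tensor elements."""
        total = 0
        for layer in self.layers:
            for value in layer.params.values():
                total += value.size
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                total += layer.moving_mean.size + layer.moving_var.size
        return total

    def get_weights(self) -> list[dict[str, np.ndarray]]:
        out = []
        for layer in self.layers:
            entry = {k: v.copy() for k, v in layer.params.items()}
            if isinstance(layer, BatchNorm):
                entry["moving_mean"] = layer.moving_mean.copy()
                entry["moving_var"] = layer.moving_var.copy()
            out.append(entry)
        return out

    def set_weights(self, weights: list[dict[str, np.ndarray]]) -> None:
        for layer, entry in zip(self.layers, weights):
            for key in layer.params:
                layer.params[key][...] = entry[key]
            if isinstance(layer, BatchNorm):
                layer.moving_mean[...] = entry["moving_mean"]
                layer.moving_var[...] = entry["moving_var"]


class Adam:
    """Adam optimizer with a mutable learning rate (for plateau schedules)."""

    def __init__(
        self,
        params: list[tuple[np.ndarray, np.ndarray]],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-7,
    ) -> None:
        self.pairs = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for (param, grad), m, v in zip(self.pairs, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * grad
            v *= self.beta2
            v += (1.0 - self.beta2) * grad * grad
            param -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)
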