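"""Declarative network plans.

A :class:`NetworkPlan` is an ordered list of :class:`LayerSpec` nodes forming a
DAG over layer indices.  The plan carries, for every layer, its output shape and
parameter count, computed by the same arithmetic a deep-learning framework
would report in its model summary:

* conv1d: ``(kernel * in_channels + 1) * filters`` (stride 1, length-preserving
  padding)
* dense: ``(in_features + 1) * units``
* batchnorm: ``4 * channels`` total (2 learned scale/shift vectors plus 2
  moving-statistic vectors; the trainable count ``2 * channels`` is reported
  separately)
* lstm: ``4 * units * (in_channels + units + 1)``; bidirectional doubles it
* pooling / dropout / flatten / concatenate: 0

Plans are purely declarative; :mod:`ecgcompress.nn.network` compiles them into
runnable layers.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

logger = logging.getLogger(__name__)

LAYER_KINDS = frozenset(
    {
        "input",
        "conv1d",
        "maxpool1d",
        "batchnorm",
        "concatenate",
        "dropout",
        "lstm",
        "bilstm",
        "flatten",
        "dense",
    }
)


class PlanError(ValueError):
    """Raised when a plan cannot be constructed (shape underflow, bad wiring)."""


@dataclass(frozen=True)
class LayerSpec:
    """One node of a network plan.

    ``output_shape`` is ``(length, channels)`` for sequence layers and
    ``(features,)`` after a flatten/dense.  ``pool`` stores the *requested*
    pool size; ``effective_pool`` the one actually applied after clamping to
    the current sequence length.
    """

    kind: str
    name: str
    inputs: tuple[int, ...]
    output_shape: tuple[int, ...]
    param_count: int = 0
    trainable_param_count: int | None = None
    filters: int | None = None
    kernel: int | None = None
    stride: int | None = None
    pool: int | None = None
    effective_pool: int | None = None
    rate: float | None = None
    units: int | None = None
    activation: str | None = None

    @property
    def trainable_params(self) -> int:
        if self.trainable_param_count is not None:
            return self.trainable_param_count
        return self.param_count


@dataclass
class NetworkPlan:
    """An ordered DAG of layer specs with a derived total parameter count."""

    layers: list[LayerSpec] = field(default_factory=list)

    @property
    def total_params(self) -> int:
        return sum(layer.param_count for layer in self.layers)

    @property
    def total_trainable_params(self) -> int:
        return sum(layer.trainable_params for layer in self.layers)

    @property
    def input_shape(self) -> tuple[int, ...]:
        return self.layers[0].output_shape

    @property
    def output_shape(self) -> tuple[int, ...]:
        return self.layers[-1].output_shape

    def __iter__(self):
        return iter(self.layers)

    def __len__(self) -> int:
        return len(self.layers)

    def __getitem__(self, idx: int) -> LayerSpec:
        return self.layers[idx]

    def kinds(self) -> list[str]:
        return [layer.kind for layer in self.layers]

    def validate(self) -> None:
        for i, layer in enumerate(self.layers):
            if layer.kind not in LAYER_KINDS:
                raise PlanError(f"layer {i} ({layer.name}): unknown kind {layer.kind!r}")
            for j in layer.inputs:
                if not 0 <= j < i:
                    raise PlanError(
                        f"layer {i} ({layer.name}): input index {j} is not upstream"
                    )

    def to_dicts(self) -> list[dict]:
        """JSON-serializable representation (for run sidecar files)."""
        return [asdict(layer) for layer in self.layers]

    @classmethod
    def from_dicts(cls, dicts: list[dict]) -> "NetworkPlan":
        layers = []
        for entry in dicts:
            entry = dict(entry)
            entry["inputs"] = tuple(entry["inputs"])
            entry["output_shape"] = tuple(entry["output_shape"])
            layers.append(LayerSpec(**entry))
        plan = cls(layers)
        plan.validate()
        return plan

    def summary_rows(self) -> list[dict]:
        """Rows for a layer-table rendering (type, config, output, params)."""
        rows = []
        for i, layer in enumerate(self.layers):
            if len(layer.output_shape) == 2:
                out = f"{layer.output_shape[0]}×{layer.output_shape[1]}"
            else:
                out = str(layer.output_shape[0])
            size = ""
            if layer.kind == "conv1d":
                size = f"{layer.kernel}, {layer.stride}"
            elif layer.kind == "maxpool1d":
                size = f"{layer.pool}, {layer.effective_pool}"
            rows.append(
                {
                    "layer": i + 1,
                    "type": layer.kind,
                    "name": layer.name,
                    "units": layer.filters or layer.units or "",
                    "size": size,
                    "output": out,
                    "params": layer.param_count,
                    "connected_to": ", ".join(str(j + 1) for j in layer.inputs),
                }
            )
        return rows


class PlanBuilder:
    """Incrementally build a :class:`NetworkPlan`, inferring shapes and params.

    Methods return the index of the appended layer so branches can be wired
    explicitly.  By default each layer consumes the previously added one.
    """

    def __init__(self) -> None:
        self.layers: list[LayerSpec] = []

    # -- helpers ---------------------------------------------------------
    def _shape(self, idx: int) -> tuple[int, ...]:
        return self.layers[idx].output_shape

    def _resolve(self, after: int | None) -> int:
        if after is None:
            after = len(self.layers) - 1
        if after < 0:
            raise PlanError("plan has no layers yet; add an input layer first")
        return after

    def _append(self, spec: LayerSpec) -> int:
        self.layers.append(spec)
        return len(self.layers) - 1

    def _seq_shape(self, idx: int, kind: str) -> tuple[int, int]:
        shape = self._shape(idx)
        if len(shape) != 2:
            raise PlanError(f"{kind} expects a (length, channels) input, got {shape}")
        return shape

    # -- layer constructors ---------------------------------------------
    def input(self, length: int, channels: int = 1, name: str = "input") -> int:
        if length < 1 or channels < 1:
            raise PlanError("input length and channels must be >= 1")
        return self._append(
            LayerSpec("input", name, (), (length, channels))
        )

    def conv1d(
        self,
        filters: int,
        kernel: int = 3,
        activation: str = "relu",
        after: int | None = None,
        name: str | None = None,
    ) -> int:
        after = self._resolve(after)
        length, in_ch = self._seq_shape(after, "conv1d")
        params = (kernel * in_ch + 1) * filters
        return self._append(
            LayerSpec(
                "conv1d",
                name or f"conv1d_{len(self.layers)}",
                (after,),
                (length, filters),
                param_count=params,
                filters=filters,
                kernel=kernel,
                stride=1,
                activation=activation,
            )
        )

    def maxpool(self, pool: int, after: int | None = None, name: str | None = None) -> int:
        after = self._resolve(after)
        length, ch = self._seq_shape(after, "maxpool1d")
        effective = min(pool, length)
        if effective < 1:
            raise PlanError(f"maxpool over empty sequence at layer {len(self.layers)}")
        if effective != pool:
            logger.info(
                "maxpool size %d clamped to %d (sequence length %d) at layer %s",
                pool,
                effective,
                length,
                name or len(self.layers),
            )
        out_len = length // effective
        return self._append(
            LayerSpec(
                "maxpool1d",
                name or f"maxpool1d_{len(self.layers)}",
                (after,),
                (out_len, ch),
                pool=pool,
                effective_pool=effective,
                stride=effective,
            )
        )

    def batchnorm(self, after: int | None = None, name: str | None = None) -> int:
        after = self._resolve(after)
        length, ch = self._seq_shape(after, "batchnorm")
        return self._append(
            LayerSpec(
                "batchnorm",
                name or f"batchnorm_{len(self.layers)}",
                (after,),
                (length, ch),
                param_count=4 * ch,
                trainable_param_count=2 * ch,
            )
        )

    def concatenate(self, inputs: tuple[int, int], name: str | None = None) -> int:
        shapes = [self._seq_shape(i, "concatenate") for i in inputs]
        channels = {ch for _, ch in shapes}
        if len(channels) != 1:
            raise PlanError(f"concatenate requires equal channel counts, got {shapes}")
        total_len = sum(length for length, _ in shapes)
        return self._append(
            LayerSpec(
                "concatenate",
                name or f"concatenate_{len(self.layers)}",
                tuple(inputs),
                (total_len, channels.pop()),
            )
        )

    def dropout(self, rate: float, after: int | None = None, name: str | None = None) -> int:
        after = self._resolve(after)
        return self._append(
            LayerSpec(
                "dropout",
                name or f"dropout_{len(self.layers)}",
                (after,),
                self._shape(after),
                rate=rate,
            )
        )

    def lstm(
        self,
        units: int,
        bidirectional: bool = False,
        after: int | None = None,
        name: str | None = None,
    ) -> int:
        after = self._resolve(after)
        length, in_ch = self._seq_shape(after, "lstm")
        per_direction = 4 * units * (in_ch + units + 1)
        kind = "bilstm" if bidirectional else "lstm"
        out_ch = 2 * units if bidirectional else units
        return self._append(
            LayerSpec(
                kind,
                name or f"{kind}_{len(self.layers)}",
                (after,),
                (length, out_ch),
                param_count=(2 if bidirectional else 1) * per_direction,
                units=units,
            )
        )

    def flatten(self, after: int | None = None, name: str | None = None) -> int:
        after = self._resolve(after)
        shape = self._shape(after)
        features = 1
        for d in shape:
            features *= d
        return self._append(
            LayerSpec(
                "flatten",
                name or f"flatten_{len(self.layers)}",
                (after,),
                (features,),
            )
        )

    def dense(
        self,
        units: int,
        activation: str | None = None,
        after: int | None = None,
        name: str | None = None,
    ) -> int:
        after = self._resolve(after)
        shape = self._shape(after)
        if len(shape) != 1:
            raise PlanError(
                f"dense expects a flat input; insert flatten before (got {shape})"
            )
        return self._append(
            LayerSpec(
                "dense",
                name or f"dense_{len(self.layers)}",
                (after,),
                (units,),
                param_count=(shape[0] + 1) * units,
                units=units,
                activation=activation,
            )
        )

    def build(self) -> NetworkPlan:
        plan = NetworkPlan(list(self.layers))
        plan.validate()
        return plan
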