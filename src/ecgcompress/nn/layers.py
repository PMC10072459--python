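"""Runtime layers: forward passes and hand-derived backward passes.

All sequence tensors are channels-last, shape ``(batch, length, channels)``.
Each layer stores its parameters in ``self.params`` and accumulates gradients
of the scalar loss in ``self.grads`` (same keys).  ``forward`` caches whatever
``backward`` needs; a layer instance therefore handles one forward/backward
pair at a time, which is all minibatch SGD requires.

Conv1d uses stride 1 with length-preserving zero padding and is evaluated as a
sum of shifted matrix products over kernel taps — for the kernel sizes used
here (3) this is faster in NumPy than an explicit im2col.  Max pooling is
valid (no padding) with stride equal to the pool size; a trailing remainder
shorter than the pool window is dropped, matching the printed shape arithmetic
260 -> 130 -> 65 -> 13 of the compression network.
"""

from __future__ import annotations

import numpy as np


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def orthogonal(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    a = rng.standard_normal(shape)
    q, r = np.linalg.qr(a if shape[0] >= shape[1] else a.T)
    q = q * np.sign(np.diag(r))
    return q if shape[0] >= shape[1] else q.T


def _apply_activation(z: np.ndarray, activation: str | None) -> np.ndarray:
    if activation is None or activation == "linear":
        return z
    if activation == "relu":
        return np.maximum(z, 0.0)
    if activation == "softmax":
        z = z - z.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)
    if activation == "tanh":
        return np.tanh(z)
    if activation == "sigmoid":
        return 1.0 / (1.0 + np.exp(-z))
    raise ValueError(f"unknown activation {activation!r}")


def _activation_backward(dy: np.ndarray, y: np.ndarray, activation: str | None) -> np.ndarray:
    """Gradient through the activation given upstream dL/dy and output y."""
    if activation is None or activation == "linear":
        return dy
    if activation == "relu":
        return dy * (y > 0.0)
    if activation == "softmax":
        # full softmax Jacobian-vector product; exact for any upstream loss
        return y * (dy - (dy * y).sum(axis=-1, keepdims=True))
    if activation == "tanh":
        return dy * (1.0 - y * y)
    if activation == "sigmoid":
        return dy * y * (1.0 - y)
    raise ValueError(f"unknown activation {activation!r}")


class Layer:
    """Base class: parameterless identity."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, xs: list[np.ndarray], training: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> list[np.ndarray]:
        raise NotImplementedError

    def zero_grads(self) -> None:
        # zero in place so optimizer-held (param, grad) aliases stay valid
        for key, value in self.params.items():
            if key in self.grads:
                self.grads[key][...] = 0.0
            else:
                self.grads[key] = np.zeros_like(value)


class InputLayer(Layer):
    def forward(self, xs, training, rng):
        return xs[0]

    def backward(self, dy):
        return [dy]


class Conv1D(Layer):
    def __init__(self, in_ch: int, filters: int, kernel: int, activation: str | None, rng: np.random.Generator) -> None:
        super().__init__()
        self.kernel = kernel
        self.activation = activation
        fan_in = kernel * in_ch
        self.params["W"] = glorot_uniform(rng, (kernel, in_ch, filters), fan_in, kernel * filters)
        self.params["b"] = np.zeros(filters)
        self.pad_left = (kernel - 1) // 2
        self.pad_right = kernel // 2
        self.zero_grads()

    def forward(self, xs, training, rng):
        (x,) = xs
        batch, length, _ = x.shape
        xp = np.pad(x, ((0, 0), (self.pad_left, self.pad_right), (0, 0)))
        z = np.broadcast_to(self.params["b"], (batch, length, self.params["b"].shape[0])).copy()
        for d in range(self.kernel):
            z += xp[:, d : d + length, :] @ self.params["W"][d]
        self._xp = xp
        self._y = _apply_activation(z, self.activation)
        return self._y

    def backward(self, dy):
        dz = _activation_backward(dy, self._y, self.activation)
        batch, length, _ = dz.shape
        dxp = np.zeros_like(self._xp)
        for d in range(self.kernel):
            self.grads["W"][d] += np.tensordot(self._xp[:, d : d + length, :], dz, axes=([0, 1], [0, 1]))
            dxp[:, d : d + length, :] += dz @ self.params["W"][d].T
        self.grads["b"] += dz.sum(axis=(0, 1))
        end = dxp.shape[1] - self.pad_right
        return [dxp[:, self.pad_left : end, :]]


class MaxPool1D(Layer):
    def __init__(self, pool: int) -> None:
        super().__init__()
        self.pool = pool

    def forward(self, xs, training, rng):
        (x,) = xs
        batch, length, ch = x.shape
        pool = min(self.pool, length)
        out_len = length // pool
        windows = x[:, : out_len * pool, :].reshape(batch, out_len, pool, ch)
        self._argmax = windows.argmax(axis=2)
        self._in_shape = x.shape
        self._pool = pool
        return np.take_along_axis(windows, self._argmax[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dy):
        batch, length, ch = self._in_shape
        out_len = dy.shape[1]
        dwin = np.zeros((batch, out_len, self._pool, ch), dtype=dy.dtype)
        np.put_along_axis(dwin, self._argmax[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        dx[:, : out_len * self._pool, :] = dwin.reshape(batch, out_len * self._pool, ch)
        return [dx]


class BatchNorm(Layer):
    """Per-channel batch normalization over (batch, length).

    Keras conventions: eps 1e-3, moving-statistics momentum 0.99.  Inference
    uses the moving mean/variance, so evaluation is deterministic.
    """

    def __init__(self, channels: int, eps: float = 1e-3, momentum: float = 0.99) -> None:
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.moving_mean = np.zeros(channels)
        self.moving_var = np.ones(channels)
        self.zero_grads()

    def forward(self, xs, training, rng):
        (x,) = xs
        if training:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.moving_mean = self.momentum * self.moving_mean + (1 - self.momentum) * mean
            self.moving_var = self.momentum * self.moving_var + (1 - self.momentum) * var
        else:
            mean, var = self.moving_mean, self.moving_var
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._inv_std
        self._training = training
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dy):
        self.grads["gamma"] += (dy * self._xhat).sum(axis=(0, 1))
        self.grads["beta"] += dy.sum(axis=(0, 1))
        dxhat = dy * self.params["gamma"]
        if not self._training:
            return [dxhat * self._inv_std]
        m = dy.shape[0] * dy.shape[1]
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 1))
            - self._xhat * (dxhat * self._xhat).mean(axis=(0, 1))
        ) * self._inv_std
        return [dx]


class Concatenate(Layer):
    """Concatenation along the time axis (axis 1)."""

    def forward(self, xs, training, rng):
        self._lengths = [x.shape[1] for x in xs]
        return np.concatenate(xs, axis=1)

    def backward(self, dy):
        out, start = [], 0
        for length in self._lengths:
            out.append(dy[:, start : start + length, :])
            start += length
        return out


class Dropout(Layer):
    def __init__(self, rate: float) -> None:
        super().__init__()
        self.rate = rate

    def forward(self, xs, training, rng):
        (x,) = xs
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return [dy]
        return [dy * self._mask]


class Flatten(Layer):
    def forward(self, xs, training, rng):
        (x,) = xs
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return [dy.reshape(self._in_shape)]


class Dense(Layer):
    def __init__(self, in_features: int, units: int, activation: str | None, rng: np.random.Generator) -> None:
        super().__init__()
        self.activation = activation
        self.params["W"] = glorot_uniform(rng, (in_features, units), in_features, units)
        self.params["b"] = np.zeros(units)
        self.zero_grads()

    def forward(self, xs, training, rng):
        (x,) = xs
        self._x = x
        self._y = _apply_activation(x @ self.params["W"] + self.params["b"], self.activation)
        return self._y

    def backward(self, dy):
        dz = _activation_backward(dy, self._y, self.activation)
        self.grads["W"] += self._x.T @ dz
        self.grads["b"] += dz.sum(axis=0)
        return [dz @ self.params["W"].T]


class LSTM(Layer):
    """Single-direction LSTM returning the full hidden sequence.

    Gate layout in the fused weight matrices is (i, f, g, o); forget-gate bias
    initialized to 1, the usual stabilizing choice.
    """

    def __init__(self, in_ch: int, units: int, rng: np.random.Generator, reverse: bool = False) -> None:
        super().__init__()
        self.units = units
        self.reverse = reverse
        self.params["Wx"] = glorot_uniform(rng, (in_ch, 4 * units), in_ch, 4 * units)
        self.params["Wh"] = orthogonal(rng, (units, 4 * units))
        bias = np.zeros(4 * units)
        bias[units : 2 * units] = 1.0
        self.params["b"] = bias
        self.zero_grads()

    def forward(self, xs, training, rng):
        (x,) = xs
        if self.reverse:
            x = x[:, ::-1, :]
        batch, steps, _ = x.shape
        u = self.units
        h = np.zeros((batch, u))
        c = np.zeros((batch, u))
        self._x = x
        self._cache = []
        hs = np.empty((batch, steps, u))
        for t in range(steps):
            z = x[:, t, :] @ self.params["Wx"] + h @ self.params["Wh"] + self.params["b"]
            i = 1.0 / (1.0 + np.exp(-z[:, :u]))
            f = 1.0 / (1.0 + np.exp(-z[:, u : 2 * u]))
            g = np.tanh(z[:, 2 * u : 3 * u])
            o = 1.0 / (1.0 + np.exp(-z[:, 3 * u :]))
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            self._cache.append((h, c, i, f, g, o, tc))
            c = c_new
            h = o * tc
            hs[:, t, :] = h
        out = hs[:, ::-1, :] if self.reverse else hs
        return out

    def backward(self, dy):
        if self.reverse:
            dy = dy[:, ::-1, :]
        batch, steps, u = dy.shape
        dx = np.zeros_like(self._x)
        dh_next = np.zeros((batch, u))
        dc_next = np.zeros((batch, u))
        for t in range(steps - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = self._cache[t]
            dh = dy[:, t, :] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            self.grads["Wx"] += self._x[:, t, :].T @ dz
            self.grads["Wh"] += h_prev.T @ dz
            self.grads["b"] += dz.sum(axis=0)
            dx[:, t, :] = dz @ self.params["Wx"].T
            dh_next = dz @ self.params["Wh"].T
            dc_next = dc * f
        if self.reverse:
            dx = dx[:, ::-1, :]
        return [dx]


class BiLSTM(Layer):
    """Two LSTMs over opposite time directions, channel-concatenated."""

    def __init__(self, in_ch: int, units: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.fwd = LSTM(in_ch, units, rng, reverse=False)
        self.bwd = LSTM(in_ch, units, rng, reverse=True)
        for key in ("Wx", "Wh", "b"):
            self.params[f"fwd_{key}"] = self.fwd.params[key]
            self.params[f"bwd_{key}"] = self.bwd.params[key]
            self.grads[f"fwd_{key}"] = self.fwd.grads[key]
            self.grads[f"bwd_{key}"] = self.bwd.grads[key]

    def zero_grads(self):
        self.fwd.zero_grads()
        self.bwd.zero_grads()
        for key in ("Wx", "Wh", "b"):
            self.grads[f"fwd_{key}"] = self.fwd.grads[key]
            self.grads[f"bwd_{key}"] = self.bwd.grads[key]

    def forward(self, xs, training, rng):
        hf = self.fwd.forward(xs, training, rng)
        hb = self.bwd.forward(xs, training, rng)
        self._units = hf.shape[-1]
        return np.concatenate([hf, hb], axis=-1)

    def backward(self, dy):
        (dxf,) = self.fwd.backward(dy[:, :, : self._units])
        (dxb,) = self.bwd.backward(dy[:, :, self._units :])
        return [dxf + dxb]
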