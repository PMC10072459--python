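"""The neural-network engine: forward-pass oracles, exact backpropagation
(checked against central finite differences), and parameter accounting."""

import numpy as np
import pytest
from scipy import signal as sp_signal

from ecgcompress.classifier import ClassifierConfig, build_classifier_plan
from ecgcompress.compression import CompressionConfig, build_compressor_plan
from ecgcompress.nn import Network, PlanBuilder


def _loss_and_grads(net: Network, x: np.ndarray):
    """L = 0.5 * sum(y^2); returns (L, input gradient) and fills param grads."""
    y = net.forward(x, training=True, rng=np.random.default_rng(123))
    net.zero_grads()
    dx = net.backward(y.copy())
    return 0.5 * float((y**2).sum()), dx


def _loss_only(net: Network, x: np.ndarray) -> float:
    y = net.forward(x, training=True, rng=np.random.default_rng(123))
    return 0.5 * float((y**2).sum())


def assert_grads_match(plan, x, eps=1e-6, tol=5e-4):
    net = Network(plan, np.random.default_rng(0))
    _, dx = _loss_and_grads(net, x)
    # input gradient
    num_dx = np.zeros_like(x)
    flat_idx = np.random.default_rng(1).choice(x.size, size=min(20, x.size), replace=False)
    for i in flat_idx:
        xp = x.copy()
        xp.flat[i] += eps
        lp = _loss_only(net, xp)
        xp.flat[i] -= 2 * eps
        lm = _loss_only(net, xp)
        num_dx.flat[i] = (lp - lm) / (2 * eps)
        np.testing.assert_allclose(dx.flat[i], num_dx.flat[i], rtol=tol, atol=tol)
    # parameter gradients
    for layer in net.layers:
        for key, param in layer.params.items():
            grad = layer.grads[key]
            idx = np.random.default_rng(2).choice(
                param.size, size=min(15, param.size), replace=False
            )
            for i in idx:
                orig = param.flat[i]
                param.flat[i] = orig + eps
                lp = _loss_only(net, x)
                param.flat[i] = orig - eps
                lm = _loss_only(net, x)
                param.flat[i] = orig
                np.testing.assert_allclose(
                    grad.flat[i], (lp - lm) / (2 * eps), rtol=tol, atol=tol,
                    err_msg=f"{type(layer).__name__}.{key}",
                )


class TestForwardOracles:
    def test_conv1d_matches_scipy_correlate(self):
        rng = np.random.default_rng(3)
        b = PlanBuilder()
        b.input(16, 1)
        b.conv1d(1, 3, activation=None)
        net = Network(b.build(), rng)
        x = rng.standard_normal((2, 16, 1))
        y = net.forward(x)
        w = net.layers[1].params["W"][:, 0, 0]
        bias = net.layers[1].params["b"][0]
        for row in range(2):
            expected = sp_signal.correlate(x[row, :, 0], w, mode="same") + bias
            np.testing.assert_allclose(y[row, :, 0], expected, atol=1e-12)

    def test_maxpool_known_values(self):
        b = PlanBuilder()
        b.input(6, 1)
        b.maxpool(2)
        net = Network(b.build(), np.random.default_rng(0))
        x = np.array([[1.0, 3.0, -1.0, 2.0, 0.0, 5.0]]).reshape(1, 6, 1)
        np.testing.assert_array_equal(net.forward(x)[0, :, 0], [3.0, 2.0, 5.0])

    def test_maxpool_drops_trailing_remainder(self):
        b = PlanBuilder()
        b.input(7, 1)
        b.maxpool(3)
        net = Network(b.build(), np.random.default_rng(0))
        x = np.arange(7.0).reshape(1, 7, 1)
        np.testing.assert_array_equal(net.forward(x)[0, :, 0], [2.0, 5.0])

    def test_softmax_rows_sum_to_one(self):
        plan = build_classifier_plan(ClassifierConfig(k=52))
        net = Network(plan, np.random.default_rng(0))
        probs = net.forward(np.random.default_rng(1).random((5, 52, 1)))
        assert probs.min() >= 0.0
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_zeroed_dense_head_gives_uniform_probabilities(self):
        plan = build_classifier_plan(ClassifierConfig(k=52))
        net = Network(plan, np.random.default_rng(0))
        head = net.layers[-1]
        head.params["W"][...] = 0.0
        head.params["b"][...] = 0.0
        probs = net.forward(np.random.default_rng(1).random((3, 52, 1)))
        np.testing.assert_allclose(probs, 0.25, atol=1e-12)

    def test_inference_is_deterministic_row_wise(self):
        plan = build_classifier_plan(ClassifierConfig(k=20))
        net = Network(plan, np.random.default_rng(0))
        x = np.random.default_rng(2).random((4, 20, 1))
        doubled = np.concatenate([x, x[:1]], axis=0)
        y = net.forward(doubled)
        np.testing.assert_array_equal(y[0], y[-1])


class TestBackprop:
    def test_conv_pool_dense_chain(self):
        b = PlanBuilder()
        b.input(12, 1)
        b.conv1d(3, 3)
        b.maxpool(2)
        b.flatten()
        b.dense(4, activation="softmax")
        assert_grads_match(b.build(), np.random.default_rng(5).standard_normal((3, 12, 1)))

    def test_batchnorm_training_mode(self):
        b = PlanBuilder()
        b.input(10, 2)
        b.batchnorm()
        b.flatten()
        b.dense(2)
        assert_grads_match(b.build(), np.random.default_rng(6).standard_normal((4, 10, 2)))

    def test_parallel_branches_with_concatenate(self):
        b = PlanBuilder()
        inp = b.input(8, 1)
        a = b.maxpool(2, after=b.conv1d(2, 3, after=inp))
        c = b.maxpool(2, after=b.conv1d(2, 3, after=inp))
        b.concatenate((a, c))
        b.flatten()
        b.dense(3, activation="softmax")
        assert_grads_match(b.build(), np.random.default_rng(7).standard_normal((2, 8, 1)))

    def test_lstm(self):
        b = PlanBuilder()
        b.input(5, 2)
        b.lstm(3)
        b.flatten()
        b.dense(2)
        assert_grads_match(b.build(), np.random.default_rng(8).standard_normal((3, 5, 2)))

    def test_bilstm(self):
        b = PlanBuilder()
        b.input(4, 2)
        b.lstm(3, bidirectional=True)
        b.flatten()
        b.dense(2)
        assert_grads_match(b.build(), np.random.default_rng(9).standard_normal((2, 4, 2)))

    def test_dropout_scales_kept_units(self):
        b = PlanBuilder()
        b.input(1000, 1)
        b.dropout(0.5)
        net = Network(b.build(), np.random.default_rng(0))
        x = np.ones((1, 1000, 1))
        y = net.forward(x, training=True, rng=np.random.default_rng(0))
        kept = y != 0.0
        np.testing.assert_allclose(y[kept], 2.0)
        assert abs(kept.mean() - 0.5) < 0.06
        # inference: identity
        np.testing.assert_array_equal(net.forward(x, training=False), x)


class TestParameterAccounting:
    @pytest.mark.parametrize("cr", [0.5, 0.4, 0.3, 0.2, 0.1, 0.05])
    def test_compressor_instantiated_count_matches_plan(self, cr):
        plan = build_compressor_plan(CompressionConfig(260, cr))
        net = Network(plan, np.random.default_rng(0))
        assert net.count_parameters() == plan.total_params

    @pytest.mark.parametrize("variant", ["full", "no_parallel", "plus_lstm", "plus_bilstm"])
    def test_classifier_instantiated_count_matches_plan(self, variant):
        plan = build_classifier_plan(ClassifierConfig(k=52, variant=variant))
        net = Network(plan, np.random.default_rng(0))
        assert net.count_parameters() == plan.total_params
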