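"""Relevance-propagation rules against hand evaluations and brute-force oracles."""

import numpy as np
import pytest

from conformotif.lrp import (Explanation, LRPConfig, LRPError,
                             conservation_report, explain, lrp_conv1d,
                             lrp_dense, lrp_maxpool, lrp_relu,
                             record_activations, seed_output_relevance)
from conformotif.network import (Conv1d, Linear, Network, NetworkSpec, ReLU,
                                 build_network, input_gradient, predict)

LRP0 = LRPConfig(rule="lrp0")


def bias_free_dense_net(sizes, seed):
    rng = np.random.default_rng(seed)
    layers = []
    for k, (n_in, n_out) in enumerate(zip(sizes[:-1], sizes[1:])):
        lin = Linear(n_in, n_out, bias=False)
        lin.W = rng.normal(size=(n_out, n_in))
        layers.append(lin)
        if k < len(sizes) - 2:
            layers.append(ReLU())
    return Network(layers)


def unrolled_conv_matrix(W, b, length, stride=1):
    """Explicit dense (C_in·L, C_out·L_out) matrix of a 1-D convolution."""
    c_out, c_in, kernel = W.shape
    l_out = (length - kernel) // stride + 1
    dense = np.zeros((c_in * length, c_out * l_out))
    bias = np.zeros(c_out * l_out)
    for o in range(c_out):
        for pos in range(l_out):
            k_up = o * l_out + pos
            if b is not None:
                bias[k_up] = b[o]
            for i in range(c_in):
                for k in range(kernel):
                    dense[i * length + pos * stride + k, k_up] = W[o, i, k]
    return dense, bias


class TestSeed:
    def test_masking(self):
        np.testing.assert_array_equal(
            seed_output_relevance(np.array([1.4, -0.2, 0.3]), 0), [1.4, 0, 0])
        np.testing.assert_array_equal(
            seed_output_relevance(np.array([1.4, -0.2, 0.3]), 2), [0, 0, 0.3])

    def test_sum_is_explained_logit(self):
        logits = np.array([0.7, -1.2, 2.5])
        for c in range(3):
            assert seed_output_relevance(logits, c).sum() == logits[c]

    def test_out_of_range_class(self):
        with pytest.raises(LRPError):
            seed_output_relevance(np.zeros(3), 3)


class TestDenseRule:
    def test_identity_layer(self):
        r = lrp_dense(np.array([2.0, 3.0]), np.eye(2), None,
                      np.array([2.0, 3.0]), LRP0)
        np.testing.assert_allclose(r, [2.0, 3.0])

    def test_basic_rule_hand_evaluation(self):
        # z = 1·1 + 3·1 = 4; shares 1/4 and 3/4 of R=4
        r = lrp_dense(np.array([1.0, 3.0]), np.array([[1.0], [1.0]]), None,
                      np.array([4.0]), LRP0)
        np.testing.assert_allclose(r, [1.0, 3.0])

    def test_epsilon_rule_hand_evaluation(self):
        # denominator 4 + 0.4 = 4.4 → (4/4.4, 12/4.4); total shrinks below 4
        r = lrp_dense(np.array([1.0, 3.0]), np.array([[1.0], [1.0]]), None,
                      np.array([4.0]), LRPConfig(epsilon=0.4))
        np.testing.assert_allclose(r, [4 / 4.4, 12 / 4.4])
        assert r.sum() < 4.0

    def test_bias_in_denominator_absorbs_relevance(self):
        # z = 2 + b(=2) = 4; propagated share is a·w/z·R = 2/4·4 = 2 < 4
        r = lrp_dense(np.array([2.0]), np.array([[1.0]]), np.array([2.0]),
                      np.array([4.0]), LRP0)
        np.testing.assert_allclose(r, [2.0])

    def test_zero_denominator_directs_to_epsilon(self):
        with pytest.raises(LRPError, match="ε rule"):
            lrp_dense(np.array([1.0, -1.0]), np.array([[1.0], [1.0]]), None,
                      np.array([1.0]), LRP0)

    def test_zero_relevance_zero_denominator_ok(self):
        r = lrp_dense(np.array([1.0, -1.0]), np.array([[1.0], [1.0]]), None,
                      np.array([0.0]), LRP0)
        np.testing.assert_array_equal(r, [0.0, 0.0])


class TestConvRule:
    def test_scalar_identity_kernel(self):
        a = np.array([[5.0, 7.0]])
        r = lrp_conv1d(a, np.ones((1, 1, 1)), None, np.array([[5.0, 7.0]]), LRP0)
        np.testing.assert_allclose(r, a)

    def test_zero_kernel_gives_zero_relevance(self):
        a = np.array([[1.0, 2.0, 3.0, 4.0]])
        r = lrp_conv1d(a, np.zeros((2, 1, 3)), None, np.zeros((2, 2)),
                       LRPConfig(epsilon=0.1))
        np.testing.assert_array_equal(r, np.zeros_like(a))

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_dense_on_unrolled_matrix(self, seed):
        rng = np.random.default_rng(seed)
        c_in, c_out, length, kernel = 2, 3, 6, 3
        a = rng.normal(size=(c_in, length))
        W = rng.normal(size=(c_out, c_in, kernel))
        b = rng.normal(size=c_out)
        r_up = rng.normal(size=(c_out, length - kernel + 1))
        cfg = LRPConfig(epsilon=0.05)
        dense_W, dense_b = unrolled_conv_matrix(W, b, length)
        expected = lrp_dense(a.reshape(-1), dense_W, dense_b,
                             r_up.reshape(-1), cfg)
        np.testing.assert_allclose(
            lrp_conv1d(a, W, b, r_up, cfg).reshape(-1), expected,
            rtol=1e-9, atol=1e-12)


class TestMaxPool:
    def test_winner_takes_all(self):
        r = lrp_maxpool(np.array([[3.0, 1.0]]), np.array([[5.0]]), window=2)
        np.testing.assert_array_equal(r, [[5.0, 0.0]])

    def test_tie_split(self):
        r = lrp_maxpool(np.array([[2.0, 2.0]]), np.array([[4.0]]), window=2)
        np.testing.assert_array_equal(r, [[2.0, 2.0]])

    def test_sum_preserved_any_window(self):
        rng = np.random.default_rng(0)
        for window in (2, 3):
            a = rng.normal(size=(4, 11))
            r_up = rng.normal(size=(4, 11 // window))
            r = lrp_maxpool(a, r_up, window)
            assert r.sum() == pytest.approx(r_up.sum(), rel=1e-12)


def test_relu_identity():
    for vec in (np.zeros(4), np.arange(4.0), np.array([-1.0, 0.0, 2.0])):
        np.testing.assert_array_equal(lrp_relu(vec), vec)


class TestTrace:
    @pytest.fixture()
    def model(self):
        return build_network(NetworkSpec(input_length=40, blocks=(3, 4),
                                         fc_sizes=(8, 3)), seed=0)

    def test_layer_inventory(self, model):
        x = np.random.default_rng(0).normal(size=40)
        trace = record_activations(model, x)
        assert len(trace.inputs) == len(model.layers)

    def test_logits_match_predict_and_purity(self, model):
        x = np.random.default_rng(1).normal(size=40)
        t1 = record_activations(model, x)
        t2 = record_activations(model, x)
        logits, _ = predict(model, x)
        np.testing.assert_array_equal(t1.logits, logits[0])
        for a, b in zip(t1.inputs, t2.inputs):
            np.testing.assert_array_equal(a, b)


class TestExplain:
    def test_zero_input_zero_relevance(self):
        net = bias_free_dense_net([4, 6, 3], seed=0)
        result = explain(net, np.zeros(4), 1, LRP0)
        np.testing.assert_array_equal(result.input_relevance, np.zeros(4))

    def test_gradient_times_input_identity(self):
        """LRP-0 on a bias-free ReLU net equals gradient×input elementwise."""
        for seed in range(5):
            net = bias_free_dense_net([6, 10, 8, 3], seed=seed)
            x = np.random.default_rng(seed + 100).normal(size=6)
            for c in range(3):
                result = explain(net, x, c, LRP0)
                gxi = input_gradient(net, x, c) * x
                np.testing.assert_allclose(result.input_relevance, gxi,
                                           rtol=1e-6, atol=1e-9)

    def test_class_maps_differ(self):
        model = build_network(NetworkSpec(input_length=30, blocks=(4,),
                                          fc_sizes=(8, 3)), seed=3)
        x = np.abs(np.random.default_rng(2).normal(size=30))
        maps = [explain(model, x, c, LRPConfig(epsilon=0.01)).input_relevance
                for c in range(3)]
        assert not np.allclose(maps[0], maps[1])
        assert not np.allclose(maps[1], maps[2])

    def test_epsilon_monotone_damping(self):
        """With all-positive denominators, larger ε weakly shrinks every |R|."""
        rng = np.random.default_rng(0)
        a = rng.uniform(0.5, 1.5, size=5)
        W = rng.uniform(0.1, 1.0, size=(5, 4))   # positive weights → z > 0
        r_up = rng.uniform(0.1, 1.0, size=4)
        previous = None
        for eps in (0.0, 0.01, 0.1, 1.0):
            r = np.abs(lrp_dense(a, W, None, r_up, LRPConfig(epsilon=eps)))
            if previous is not None:
                assert np.all(r <= previous + 1e-12)
            previous = r


class TestConservation:
    def test_bias_free_toy_net_conserves_seed(self):
        net = bias_free_dense_net([3, 5, 4, 3], seed=1)
        x = np.random.default_rng(7).normal(size=3)
        for c in range(3):
            result = explain(net, x, c, LRP0)
            if abs(result.seed) < 1e-9:
                continue
            report = conservation_report(result)
            assert (report.deficit.abs().max() / abs(result.seed)) <= 1e-9

    def test_pooling_layers_zero_deficit(self):
        model = build_network(NetworkSpec(input_length=20, blocks=(2,),
                                          fc_sizes=(4, 3)), seed=0)
        # bias-free variant of the CNN: zero all biases
        for layer in model.layers:
            if hasattr(layer, "b") and layer.b is not None:
                layer.b[...] = 0.0
        x = np.abs(np.random.default_rng(3).normal(size=20))
        result = explain(model, x, 0, LRP0)
        report = conservation_report(result)
        sums = dict(zip(report.layer, report.relevance_sum))
        # pooling redistributes without loss: sum before == sum after
        names = list(report.layer)
        for k, name in enumerate(names[:-1]):
            if name == "MaxPool1d":
                assert report.relevance_sum[k] == pytest.approx(
                    report.relevance_sum[k + 1], rel=1e-9, abs=1e-12)
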