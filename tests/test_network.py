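"""Architecture arithmetic, forward/backward correctness, training, metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conformotif.labeling import STATES
from conformotif.network import (Network, NetworkError, NetworkSpec, TrainConfig,
                                 build_network, conv_output_length, evaluate,
                                 input_gradient, layer_summary, parameter_count,
                                 pool_output_length, predict,
                                 report_from_predictions, softmax_cross_entropy,
                                 train)


class TestShapeArithmetic:
    @pytest.mark.parametrize("length, kernel, expected", [
        (846, 3, 844), (422, 3, 420), (420, 3, 418), (210, 3, 208),
    ])
    def test_conv_lengths(self, length, kernel, expected):
        assert conv_output_length(length, kernel) == expected

    def test_kernel_one_is_identity(self):
        assert conv_output_length(123, 1) == 123

    @pytest.mark.parametrize("length, window, expected", [
        (844, 2, 422), (102, 2, 51), (5, 2, 2),
    ])
    def test_pool_lengths(self, length, window, expected):
        assert pool_output_length(length, window) == expected

    def test_degenerate_conv_raises(self):
        with pytest.raises(NetworkError, match="lose"):
            conv_output_length(2, 3)

    @settings(derandomize=True, max_examples=50)
    @given(
        input_length=st.integers(min_value=40, max_value=400),
        blocks=st.lists(st.sampled_from([2, 4, 8]), min_size=1, max_size=3),
        fc=st.sampled_from([8, 16]),
    )
    def test_declared_shapes_match_forward_pass(self, input_length, blocks, fc):
        """Shape recursion equals shapes observed in an actual forward pass."""
        spec = NetworkSpec(input_length=input_length, blocks=tuple(blocks),
                           fc_sizes=(fc, 3))
        model = build_network(spec, seed=0)
        x = np.random.default_rng(1).normal(size=(2, input_length))
        h = model._prepare(x)
        conv_pool = iter(spec.block_lengths())
        for layer in model.layers:
            h = layer.forward(h)
        assert h.shape == (2, 3)
        # per-layer parameter declaration equals actual trainable scalars
        declared, total = parameter_count(spec)
        assert total == model.n_parameters()


class TestParameterCount:
    def test_default_spec_per_layer(self):
        per_layer, _ = parameter_count(NetworkSpec())
        assert per_layer["Conv1d-1"] == 256
        assert per_layer["Linear-1"] == 26_739_712
        assert per_layer["Linear-2"] == 3075

    def test_pooling_and_activation_free(self):
        rows = layer_summary(NetworkSpec())
        for row in rows:
            if any(tag in row["layer"] for tag in ("Pool", "ReLU", "Dropout", "Flatten")):
                assert row["params"] == 0


class TestBuildNetwork:
    def test_default_flatten_length(self):
        spec = NetworkSpec()
        assert spec.flatten_length == 26_112
        model = build_network(NetworkSpec(input_length=60, blocks=(4,),
                                          fc_sizes=(8, 3)), seed=0)
        logits = model.forward(np.zeros((1, 60)))
        assert logits.shape == (1, 3)

    def test_same_seed_bit_identical(self):
        spec = NetworkSpec(input_length=60, blocks=(4, 8), fc_sizes=(16, 3))
        a = build_network(spec, seed=42)
        b = build_network(spec, seed=42)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa, pb)

    def test_five_blocks_valid_but_overdeep_raises(self):
        # 846 survives five blocks (…51→49→24) …
        build_network(NetworkSpec(blocks=(4, 4, 4, 4, 4), fc_sizes=(8, 3)), seed=0)
        # … but a spec that shrinks below the kernel length must refuse
        with pytest.raises(NetworkError):
            build_network(NetworkSpec(input_length=10, blocks=(4, 4, 4),
                                      fc_sizes=(8, 3)), seed=0)


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Analytic loss gradients agree with central differences."""
        spec = NetworkSpec(input_length=20, blocks=(3,), fc_sizes=(6, 3),
                           dropout=0.0)
        model = build_network(spec, seed=0)
        rng = np.random.default_rng(1)
        X = rng.normal(size=(4, 20))
        y = np.array([0, 1, 2, 1])

        logits = model.forward(X, training=True)
        _, grad_logits = softmax_cross_entropy(logits, y)
        model.backward(grad_logits)
        analytic = [g.copy() for g in model.gradients()]

        def loss_value():
            l, _ = softmax_cross_entropy(model.forward(X, training=True), y)
            return l

        eps = 1e-6
        for p, g in zip(model.parameters(), analytic):
            flat = p.reshape(-1)
            n_probe = min(5, flat.size)
            for idx in np.random.default_rng(2).choice(flat.size, n_probe,
                                                       replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss_value()
                flat[idx] = orig - eps
                down = loss_value()
                flat[idx] = orig
                assert g.reshape(-1)[idx] == pytest.approx(
                    (up - down) / (2 * eps), rel=1e-4, abs=1e-7)

    def test_input_gradient_shape(self):
        model = build_network(NetworkSpec(input_length=30, blocks=(4,),
                                          fc_sizes=(8, 3)), seed=0)
        g = input_gradient(model, np.ones(30), class_idx=2)
        assert g.shape == (30,)


class TestTraining:
    def test_zero_epochs_leaves_weights(self):
        spec = NetworkSpec(input_length=12, blocks=(2,), fc_sizes=(4, 3))
        model = build_network(spec, seed=0)
        before = [p.copy() for p in model.parameters()]
        train(model, np.zeros((6, 12)), np.zeros(6, int),
              TrainConfig(epochs=0, batch_size=2, learning_rate=1e-3))
        for p0, p1 in zip(before, model.parameters()):
            np.testing.assert_array_equal(p0, p1)

    def test_loss_descends_from_initial(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(90, 24))
        y = rng.integers(0, 3, 90)
        X[np.arange(90), y] += 3.0
        spec = NetworkSpec(input_length=24, blocks=(4,), fc_sizes=(8, 3),
                           dropout=0.0)
        model = build_network(spec, seed=0)
        initial_loss, _ = softmax_cross_entropy(model.forward(X), y)
        train(model, X, y, TrainConfig(epochs=3, batch_size=32,
                                       learning_rate=1e-3, seed=0))
        assert model.history["loss"][-1] < initial_loss

    def test_separable_data_learned_quickly(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 3, 240)
        X = rng.normal(size=(240, 30)) * 0.1
        X[np.arange(240), y * 3] += 2.0
        model = build_network(NetworkSpec(input_length=30, blocks=(8,),
                                          fc_sizes=(16, 3)), seed=1)
        train(model, X, y, TrainConfig(epochs=50, batch_size=64,
                                       learning_rate=1e-3, seed=1))
        assert evaluate(model, X, y).accuracy >= 0.99


class TestPredictEvaluate:
    def test_argmax_and_tiebreak(self):
        class Fixed(Network):
            def forward(self, X, training=False, rng=None):
                return np.asarray(X, dtype=float)

        model = Fixed([])
        logits = np.array([[2.0, 0.1, -1.0], [1.0, 1.0, 0.0]])
        _, yhat = predict(model, logits)
        assert yhat.tolist() == [0, 0]  # tie broken toward lowest class index

    def test_batch_order_preserved(self):
        model = build_network(NetworkSpec(input_length=12, blocks=(2,),
                                          fc_sizes=(4, 3)), seed=0)
        X = np.random.default_rng(0).normal(size=(5, 12))
        logits, yhat = predict(model, X)
        assert logits.shape == (5, 3) and yhat.shape == (5,)
        single = [predict(model, X[k:k + 1])[1][0] for k in range(5)]
        assert yhat.tolist() == single

    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        report = report_from_predictions(y, y)
        assert report.accuracy == 1.0 and report.macro_f1 == 1.0
        np.testing.assert_array_equal(report.confusion_normalized, np.eye(3))

    def test_constant_predictor_closed_form(self):
        y = np.repeat([0, 1, 2], 10)
        report = report_from_predictions(y, np.zeros(30, int))
        assert report.accuracy == pytest.approx(1 / 3)
        assert report.recall[0] == 1.0
        assert report.precision[0] == pytest.approx(1 / 3)

    def test_hand_confusion_matrix_metrics(self):
        """Metrics recomputed from first principles on a printed matrix."""
        cm = np.array([[8, 1, 1], [2, 6, 2], [0, 3, 7]])
        y_true = np.repeat([0, 1, 2], 10)
        y_pred = np.concatenate([
            np.repeat([0, 1, 2], cm[0]), np.repeat([0, 1, 2], cm[1]),
            np.repeat([0, 1, 2], cm[2])])
        report = report_from_predictions(y_true, y_pred)
        # independent oracle: the standard formulas evaluated by hand
        col = cm.sum(axis=0)
        for c in range(3):
            precision = cm[c, c] / col[c]
            recall = cm[c, c] / 10
            f1 = 2 * precision * recall / (precision + recall)
            assert report.precision[c] == pytest.approx(precision)
            assert report.recall[c] == pytest.approx(recall)
            assert report.f1[c] == pytest.approx(f1)
        assert report.accuracy == pytest.approx(21 / 30)
        assert report.macro_f1 == pytest.approx(np.mean(report.f1))
        np.testing.assert_allclose(report.confusion_normalized.sum(axis=1),
                                   np.ones(3))

    def test_empty_input_rejected(self):
        model = build_network(NetworkSpec(input_length=12, blocks=(2,),
                                          fc_sizes=(4, 3)), seed=0)
        with pytest.raises(NetworkError):
            evaluate(model, np.zeros((0, 12)), np.zeros(0, int))


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path):
        spec = NetworkSpec(input_length=18, blocks=(3,), fc_sizes=(5, 3))
        model = build_network(spec, seed=4)
        X = np.random.default_rng(0).normal(size=(3, 18))
        path = tmp_path / "model.npz"
        model.save(path)
        back = Network.load(path)
        np.testing.assert_array_equal(model.forward(X), back.forward(X))
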