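"""Architecture audit, unit functions, gradients, and training behavior."""

from decimal import Decimal, getcontext

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from stooltrait.errors import InvalidInputError
from stooltrait.trait_cnn import (
    NetworkConfig,
    ShallowCNN,
    TrainConfig,
    build_model,
    cross_entropy_loss,
    default_filters,
    evaluate,
    load_model,
    predict,
    relu,
    save_model,
    softmax,
    train,
)

# closed-form parameter count of the default architecture:
# three 3x3 conv layers (32, 64, 256 filters), 7x7x256 flatten, FC 256, FC 5
DEFAULT_PARAMS = (
    (3 * 3 * 3 * 32 + 32)
    + (3 * 3 * 32 * 64 + 64)
    + (3 * 3 * 64 * 256 + 256)
    + (7 * 7 * 256 * 256 + 256)
    + (256 * 5 + 5)
)


class TestArchitecture:
    def test_default_config_audit(self):
        cfg = NetworkConfig()
        assert cfg.kernel_size == 3
        assert cfg.conv_filters == (32, 64, 256)
        assert cfg.fc_size == 256
        assert cfg.num_classes == 5
        assert cfg.spatial_trace() == [(30, 30), (15, 15), (7, 7)]

    def test_parameter_count_closed_form(self):
        assert build_model(NetworkConfig()).parameter_count() == DEFAULT_PARAMS

    def test_depth_one_builds(self):
        model = build_model(NetworkConfig(depth=1))
        x = np.zeros((2, 60, 60, 3), np.float32)
        logits, _ = model.forward(x)
        assert logits.shape == (2, 5)

    def test_depth_schedule(self):
        assert default_filters(1) == (32,)
        assert default_filters(2) == (32, 64)
        assert default_filters(5) == (32, 64, 256, 512, 1024)

    def test_invalid_depth_rejected(self):
        with pytest.raises(InvalidInputError):
            NetworkConfig(depth=0)

    def test_pooling_skipped_at_unit_size(self):
        # 60 -> 30 -> 15 -> 7 -> 3 -> 1 -> 1 (no pooling below 2x2)
        cfg = NetworkConfig(depth=6)
        assert cfg.spatial_trace()[-2:] == [(1, 1), (1, 1)]
        logits, _ = build_model(cfg).forward(np.zeros((1, 60, 60, 3), np.float32))
        assert logits.shape == (1, 5)


class TestUnitFunctions:
    @pytest.mark.parametrize("x, y", [(-3.0, 0.0), (5.0, 5.0)])
    def test_relu_scalars(self, x, y):
        assert relu(np.array(x)) == y

    def test_relu_vector(self):
        np.testing.assert_array_equal(relu(np.array([-1.0, 0.0, 2.0])), [0.0, 0.0, 2.0])

    def test_softmax_uniform(self):
        np.testing.assert_allclose(softmax(np.zeros(5)), np.full(5, 0.2))

    def test_softmax_dominance_without_overflow(self):
        p = softmax(np.array([1000.0, 0, 0, 0, 0]))
        assert np.isfinite(p).all()
        assert p[0] == pytest.approx(1.0)

    def test_softmax_against_high_precision_oracle(self):
        getcontext().prec = 50
        y = [1, 2, 3, 4, 5]
        es = [Decimal(v).exp() for v in y]
        expected = [float(e / sum(es)) for e in es]
        np.testing.assert_allclose(softmax(np.array(y, dtype=float)), expected, rtol=1e-12)

    @given(hst.lists(hst.floats(-50, 50), min_size=2, max_size=8),
           hst.floats(-100, 100))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_softmax_shift_invariance_and_normalization(self, ys, c):
        y = np.array(ys)
        p = softmax(y)
        assert p.sum() == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_allclose(p, softmax(y + c), atol=1e-9)

    def test_loss_perfect_prediction_is_zero(self):
        p = np.eye(5)[[0, 3]]
        assert cross_entropy_loss(p, p) == pytest.approx(0.0, abs=1e-9)

    def test_loss_uniform_prediction_is_log5(self):
        p = np.eye(5)[[2]]
        q = np.full((1, 5), 0.2)
        assert cross_entropy_loss(p, q) == pytest.approx(np.log(5))

    def test_loss_two_sample_hand_arithmetic(self):
        p = np.eye(5)[[0, 4]]
        q = np.array([[0.7, 0.1, 0.1, 0.05, 0.05],
                      [0.2, 0.2, 0.2, 0.2, 0.2]])
        expected = (-np.log(0.7) - np.log(0.2)) / 2  # mean over the batch
        assert cross_entropy_loss(p, q) == pytest.approx(expected)

    def test_loss_clamps_zero_probability(self):
        p = np.eye(5)[[1]]
        q = np.zeros((1, 5))
        q[0, 0] = 1.0
        out = cross_entropy_loss(p, q)
        assert np.isfinite(out) and out > 20  # -log(1e-12)

    def test_loss_nonnegative(self, rng):
        for _ in range(20):
            q = softmax(rng.normal(size=(4, 5)))
            p = np.eye(5)[rng.integers(0, 5, 4)]
            assert cross_entropy_loss(p, q) >= 0


def _tiny_model(dtype=np.float64):
    cfg = NetworkConfig(input_size=(8, 8, 3), depth=2, conv_filters=(4, 6),
                        fc_size=10, num_classes=3, dropout_rate=0.0)
    return ShallowCNN(cfg, seed=0, dtype=dtype)


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng):
        model = _tiny_model()
        x = rng.random((4, 8, 8, 3))
        y = np.array([0, 1, 2, 1])
        onehot = np.eye(3)[y]

        logits, cache = model.forward(x, training=True, rng=rng)
        probs = softmax(logits)
        grads = model.backward(cache, (probs - onehot) / len(x))

        def loss_at_params():
            lg, _ = model.forward(x)
            return cross_entropy_loss(onehot, softmax(lg))

        for name, p in model.params.items():
            for _ in range(4):
                idx = tuple(rng.integers(0, s) for s in p.shape)
                eps, old = 1e-6, p[idx]
                p[idx] = old + eps
                lp = loss_at_params()
                p[idx] = old - eps
                lm = loss_at_params()
                p[idx] = old
                num = (lp - lm) / (2 * eps)
                assert grads[name][idx] == pytest.approx(num, abs=1e-7), name


def _separable_data(n=200, size=12, num_classes=3, seed=0):
    """Solid-color images, one color per class: trivially separable."""
    rng = np.random.default_rng(seed)
    colors = np.array([[0.9, 0.1, 0.1], [0.1, 0.9, 0.1], [0.1, 0.1, 0.9]])
    y = rng.integers(0, num_classes, n)
    x = np.empty((n, size, size, 3), np.float32)
    for i, c in enumerate(y):
        x[i] = colors[c] + rng.normal(0, 0.03, (size, size, 3))
    return x.clip(0, 1), y


class TestTraining:
    def test_fits_separable_data(self):
        x, y = _separable_data()
        cfg = NetworkConfig(input_size=(12, 12, 3), depth=2, conv_filters=(8, 16),
                            fc_size=32, num_classes=3)
        model = build_model(cfg, seed=0)
        history = train(model, x, y, TrainConfig(epochs=10, seed=0,
                                                 early_stopping_patience=None))
        acc, _ = evaluate(model, x, y)  # dropout inactive at evaluation
        assert acc >= 0.99
        assert history[-1]["loss"] < history[0]["loss"]

    def test_training_is_deterministic(self):
        x, y = _separable_data(n=40)
        cfg = NetworkConfig(input_size=(12, 12, 3), depth=1, conv_filters=(4,),
                            fc_size=8, num_classes=3)
        finals = []
        for _ in range(2):
            model = build_model(cfg, seed=7)
            train(model, x, y, TrainConfig(epochs=2, seed=7,
                                           early_stopping_patience=None))
            finals.append({k: v.copy() for k, v in model.params.items()})
        for k in finals[0]:
            np.testing.assert_array_equal(finals[0][k], finals[1][k])

    def test_zero_learning_rate_freezes_weights(self):
        x, y = _separable_data(n=20)
        cfg = NetworkConfig(input_size=(12, 12, 3), depth=1, conv_filters=(4,),
                            fc_size=8, num_classes=3, dropout_rate=0.0)
        model = build_model(cfg, seed=1)
        before = {k: v.copy() for k, v in model.params.items()}
        history = train(model, x, y, TrainConfig(learning_rate=0.0, epochs=3, seed=0,
                                                 early_stopping_patience=None))
        for k in before:
            np.testing.assert_array_equal(before[k], model.params[k])
        losses = [h["loss"] for h in history]
        assert max(losses) - min(losses) < 1e-6

    def test_single_class_warns(self):
        x, y = _separable_data(n=10)
        y[:] = 0
        cfg = NetworkConfig(input_size=(12, 12, 3), depth=1, conv_filters=(4,),
                            fc_size=8, num_classes=3)
        with pytest.warns(UserWarning, match="single class"):
            train(build_model(cfg, seed=0), x, y,
                  TrainConfig(epochs=1, seed=0, early_stopping_patience=None))

    def test_empty_training_set_rejected(self):
        cfg = NetworkConfig(input_size=(12, 12, 3), depth=1, conv_filters=(4,),
                            fc_size=8, num_classes=3)
        with pytest.raises(InvalidInputError):
            train(build_model(cfg), np.zeros((0, 12, 12, 3)), np.zeros(0),
                  TrainConfig(epochs=1))


class TestEvaluatePredict:
    def test_constant_predictor_on_balanced_set(self):
        model = _tiny_model(dtype=np.float32)
        for k, v in model.params.items():  # zero weights -> uniform output, argmax 0
            model.params[k] = np.zeros_like(v)
        x = np.random.default_rng(0).random((30, 8, 8, 3)).astype(np.float32)
        y = np.repeat(np.arange(3), 10)
        acc, cm = evaluate(model, x, y)
        assert acc == pytest.approx(1 / 3)
        assert cm[:, 0].sum() == 30  # every prediction lands in column 0
        assert cm.sum() == 30

    def test_confusion_diagonal_for_perfect_fit(self):
        x, y = _separable_data(n=60)
        cfg = NetworkConfig(input_size=(12, 12, 3), depth=2, conv_filters=(8, 16),
                            fc_size=32, num_classes=3)
        model = build_model(cfg, seed=0)
        train(model, x, y, TrainConfig(epochs=10, seed=0, early_stopping_patience=None))
        acc, cm = evaluate(model, x, y)
        assert acc == pytest.approx(np.trace(cm) / cm.sum())
        assert cm.shape == (3, 3)

    def test_predict_single_image(self):
        model = _tiny_model(dtype=np.float32)
        res = predict(model, np.zeros((8, 8, 3), np.uint8))
        assert res.probs.shape == (3,)
        assert res.probs.sum() == pytest.approx(1.0, abs=1e-6)
        assert res.predicted == int(res.probs.argmax())

    def test_save_load_round_trip(self, tmp_path, rng):
        model = _tiny_model(dtype=np.float32)
        x = rng.random((3, 8, 8, 3)).astype(np.float32)
        save_model(model, tmp_path / "m.npz")
        loaded = load_model(tmp_path / "m.npz")
        np.testing.assert_array_equal(
            model.predict_proba(x), loaded.predict_proba(x)
        )
        assert loaded.cfg == model.cfg
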