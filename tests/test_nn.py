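"""Stream classifiers: structure, gradients, training, inference contracts."""

import numpy as np
import pytest

from feedstream.nn import (
    Conv1dNetConfig,
    NetworkError,
    ResidualBackboneConfig,
    Sequential,
    TrainConfig,
    build_conv1d_net,
    build_residual_backbone,
    load_model_weights,
    predict_proba,
    predict_stream,
    save_model,
    softmax_cross_entropy,
    train_stream,
)
from feedstream.nn.layers import (
    BatchNorm,
    Conv2d,
    Dense,
    GlobalAvgPool2d,
    MaxPool2d,
    ReLU,
)
from feedstream.nn.resnet import ResidualBlock


class TestBackboneStructure:
    def test_canonical_block_counts_give_49_convolutions(self):
        _, summary = build_residual_backbone(ResidualBackboneConfig())
        assert summary["conv_layers"] == 49
        assert summary["weighted_layers"] == 50

    def test_224_input_reaches_pooling_at_7x7x2048(self):
        _, summary = build_residual_backbone(ResidualBackboneConfig())
        assert summary["prepool_shape"] == (7, 7, 2048)

    def test_minimal_block_counts_give_13_convolutions(self):
        cfg = ResidualBackboneConfig(stage_block_counts=(1, 1, 1, 1))
        _, summary = build_residual_backbone(cfg)
        assert summary["conv_layers"] == 13

    @pytest.mark.parametrize("blocks", [(2, 2, 2, 2), (1, 2, 3, 1)])
    def test_layer_count_formula_for_any_blocks(self, blocks):
        cfg = ResidualBackboneConfig(
            stage_block_counts=blocks, input_size=(64, 64, 3), base_width=4
        )
        model, summary = build_residual_backbone(cfg)
        assert summary["conv_layers"] == 1 + 3 * sum(blocks)
        # count actual convolution layers on the main paths
        n_convs = 1  # stem
        for layer in model.layers:
            if isinstance(layer, ResidualBlock):
                n_convs += sum(isinstance(l, Conv2d) for l in layer.main.layers)
        assert n_convs == summary["conv_layers"]

    def test_reduced_profile_shapes(self):
        cfg = ResidualBackboneConfig(
            stage_block_counts=(1, 1, 1, 1), input_size=(64, 64, 3), base_width=8
        )
        model, summary = build_residual_backbone(cfg)
        assert summary["prepool_shape"] == (2, 2, 256)
        out = model.forward(np.zeros((2, 3, 64, 64)), train=False)
        assert out.shape == (2, 3)

    def test_invalid_blocks_rejected(self):
        with pytest.raises(NetworkError):
            ResidualBackboneConfig(stage_block_counts=(0, 1, 1, 1))


class TestConv1dNet:
    def test_forward_scores_normalized(self, rng):
        model = build_conv1d_net(Conv1dNetConfig(), seed=0)
        probs = predict_proba(model, rng.normal(size=(5, 1, 16)))
        assert probs.shape == (5, 3)
        assert (probs >= 0).all()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0)

    def test_inference_deterministic(self, rng):
        model = build_conv1d_net(Conv1dNetConfig(), seed=0)
        x = rng.normal(size=(3, 1, 16))
        np.testing.assert_array_equal(predict_proba(model, x), predict_proba(model, x))

    def test_duplicated_input_gives_identical_rows(self, rng):
        model = build_conv1d_net(Conv1dNetConfig(), seed=1)
        x = rng.normal(size=(1, 1, 16))
        probs = predict_proba(model, np.concatenate([x, x]))
        np.testing.assert_allclose(probs[0], probs[1])

    def test_kernel_wider_than_input_rejected(self):
        with pytest.raises(NetworkError):
            build_conv1d_net(Conv1dNetConfig(input_length=4, conv_blocks=((8, 3, 2), (8, 3, 2), (8, 3, 2))))


def _numeric_grad_matches(model: Sequential, x, y, rng, n_checks=4, tol=1e-4):
    logits = model.forward(x, train=True)
    _, dlogits = softmax_cross_entropy(logits, y)
    for p in model.params():
        p.grad[...] = 0.0
    model.backward(dlogits)
    for p in model.params():
        for _ in range(n_checks):
            idx = tuple(rng.integers(0, s) for s in p.value.shape)
            eps = 1e-6
            orig = p.value[idx]
            p.value[idx] = orig + eps
            up, _ = softmax_cross_entropy(model.forward(x, train=True), y)
            p.value[idx] = orig - eps
            down, _ = softmax_cross_entropy(model.forward(x, train=True), y)
            p.value[idx] = orig
            numeric = (up - down) / (2 * eps)
            if abs(numeric) < 5e-7 and abs(p.grad[idx]) < 5e-7:
                continue  # both zero up to finite-difference noise
            scale = max(abs(numeric) + abs(p.grad[idx]), 1e-6)
            if abs(numeric - p.grad[idx]) / scale > tol:
                return False, (p.name, idx, numeric, p.grad[idx])
    return True, None


class TestGradients:
    def test_conv_bn_pool_dense_chain(self, rng):
        model = Sequential(
            [
                Conv2d(3, 4, 3, stride=1, pad=1, rng=rng),
                BatchNorm(4),
                ReLU(),
                MaxPool2d(),
                Conv2d(4, 6, 3, stride=2, pad=1, rng=rng),
                BatchNorm(6),
                ReLU(),
                GlobalAvgPool2d(),
                Dense(6, 3, rng=rng),
            ]
        )
        x = rng.normal(size=(4, 3, 16, 16))
        ok, detail = _numeric_grad_matches(model, x, np.array([0, 1, 2, 0]), rng)
        assert ok, detail

    def test_residual_block_with_projection(self, rng):
        model = Sequential(
            [ResidualBlock(3, 4, 2, True, rng), GlobalAvgPool2d(), Dense(16, 3, rng=rng)]
        )
        x = rng.normal(size=(3, 3, 12, 12))
        ok, detail = _numeric_grad_matches(model, x, np.array([0, 1, 2]), rng)
        assert ok, detail

    def test_conv1d_network(self, rng):
        model = build_conv1d_net(Conv1dNetConfig(), seed=3)
        x = rng.normal(size=(5, 1, 16))
        ok, detail = _numeric_grad_matches(model, x, np.array([0, 1, 2, 1, 0]), rng)
        assert ok, detail


def separable_vectors(rng, n_per_class=30):
    """Three Gaussian blobs far apart in 16-D."""
    X, y = [], []
    for c in range(3):
        center = np.zeros(16)
        center[c * 5] = 4.0
        X.append(rng.normal(size=(n_per_class, 16)) * 0.3 + center)
        y += [c] * n_per_class
    return np.concatenate(X)[:, None, :], np.array(y)


class TestTraining:
    def test_zero_epochs_rejected(self):
        with pytest.raises(NetworkError, match="epochs"):
            TrainConfig(epochs=0)

    def test_missing_class_rejected(self, rng):
        model = build_conv1d_net(Conv1dNetConfig(), seed=0)
        X = rng.normal(size=(10, 1, 16))
        y = np.array([0, 1] * 5)  # class 'strong' absent
        with pytest.raises(NetworkError, match="strong"):
            train_stream(model, X, y, TrainConfig(epochs=1))

    def test_separable_set_reaches_high_train_accuracy(self, rng):
        X, y = separable_vectors(rng)
        model = build_conv1d_net(Conv1dNetConfig(), seed=0)
        history = train_stream(model, X, y, TrainConfig(epochs=15, seed=0))
        assert len(history) == 15
        assert history["train_loss"].notna().all()
        assert np.isfinite(history["train_loss"]).all()
        assert history["train_acc"].iloc[-1] >= 0.95

    def test_fixed_seed_reproduces_training(self, rng):
        X, y = separable_vectors(rng, n_per_class=10)
        runs = []
        for _ in range(2):
            model = build_conv1d_net(Conv1dNetConfig(), seed=5)
            hist = train_stream(model, X, y, TrainConfig(epochs=3, seed=5))
            runs.append((hist, predict_proba(model, X)))
        assert runs[0][0].equals(runs[1][0])
        np.testing.assert_array_equal(runs[0][1], runs[1][1])

    def test_history_includes_validation_when_given(self, rng):
        X, y = separable_vectors(rng, n_per_class=8)
        model = build_conv1d_net(Conv1dNetConfig(), seed=0)
        hist = train_stream(model, X, y, TrainConfig(epochs=2), X_val=X[:6], y_val=y[:6])
        assert {"val_loss", "val_acc"} <= set(hist.columns)


class TestPredictAndPersistence:
    def test_predict_stream_contract(self, rng):
        model = build_conv1d_net(Conv1dNetConfig(), seed=0)
        pred = predict_stream(model, rng.normal(size=(1, 16)))
        assert pred.scores.shape == (3,)
        assert pred.argmax_label in ("none", "weak", "strong")

    def test_save_load_roundtrip(self, tmp_path, rng):
        X, y = separable_vectors(rng, n_per_class=5)
        model = build_conv1d_net(Conv1dNetConfig(), seed=2)
        train_stream(model, X, y, TrainConfig(epochs=2, seed=2))
        before = predict_proba(model, X)
        save_model(model, tmp_path / "m.npz", summary={"type": "conv1d"})
        fresh = build_conv1d_net(Conv1dNetConfig(), seed=99)
        load_model_weights(fresh, tmp_path / "m.npz")
        np.testing.assert_allclose(predict_proba(fresh, X), before)
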