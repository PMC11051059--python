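"""CNN architecture, training behavior, serialization, and edge inference."""

import json

import numpy as np
import pytest

from ecgedge.model import (
    FormatError,
    NumpyCnn,
    Prediction,
    build_model,
    export_json,
    import_json,
    infer,
    parameter_count,
    predict_proba,
    train_model,
)
from ecgedge.model.architecture import CnnSpec, SpecError, TrainConfig
from ecgedge.model.network import TrainingError

TOY = CnnSpec(
    input_height=16, input_width=16, n_blocks=2, filters=3,
    dense1=5, dense2=4, dropout_rate=0.0,
)


def _rand_images(n, h=128, w=96, seed=0, density=0.06):
    rng = np.random.default_rng(seed)
    return (rng.random((n, h, w)) < density).astype(np.float32)


class TestArchitecture:
    def test_default_parameter_count_closed_form(self):
        # independent layer-shape sum: conv1 + 3 deeper convs + head
        expected = (3 * 3 * 1 * 64 + 64) + 3 * (3 * 3 * 64 * 64 + 64)
        expected += (8 * 6 * 64) * 128 + 128
        expected += 128 * 64 + 64
        expected += 64 * 2 + 2
        assert expected == 513154
        assert parameter_count(CnnSpec()) == expected
        assert build_model(CnnSpec(), seed=0).n_parameters() == expected

    def test_flatten_size_for_smaller_input(self):
        assert CnnSpec(input_height=64, input_width=48).flatten_size == 4 * 3 * 64

    def test_indivisible_input_rejected(self):
        with pytest.raises(SpecError):
            CnnSpec(input_height=100).validate()

    def test_seeded_init_reproducible(self):
        a = build_model(CnnSpec(), seed=7)
        b = build_model(CnnSpec(), seed=7)
        c = build_model(CnnSpec(), seed=8)
        for k in a.weights:
            np.testing.assert_array_equal(a.weights[k], b.weights[k])
        assert any(not np.array_equal(a.weights[k], c.weights[k]) for k in a.weights)


class TestTraining:
    def test_zero_epochs_keeps_initial_weights(self):
        bundle = build_model(TOY, seed=0)
        before = bundle.copy_weights()
        x = _rand_images(8, 16, 16)
        y = np.array([0, 1] * 4)
        trained, history = train_model(bundle, x, y, x[:4], y[:4], TrainConfig(epochs=0))
        assert history == []
        for k in before:
            np.testing.assert_array_equal(trained.weights[k], before[k])

    def test_single_class_labels_refused(self):
        bundle = build_model(TOY, seed=0)
        x = _rand_images(8, 16, 16)
        with pytest.raises(TrainingError, match="single class"):
            train_model(bundle, x, np.ones(8, dtype=int), x[:4], np.ones(4, dtype=int))

    def test_training_is_seed_reproducible(self):
        x = _rand_images(16, 16, 16, seed=3)
        y = np.array([0, 1] * 8)
        cfg = TrainConfig(epochs=2, batch_size=8, seed=4)
        a, _ = train_model(build_model(TOY, seed=1), x, y, x[:4], y[:4], cfg)
        b, _ = train_model(build_model(TOY, seed=1), x, y, x[:4], y[:4], cfg)
        for k in a.weights:
            np.testing.assert_array_equal(a.weights[k], b.weights[k])

    def test_loss_decreases_on_separable_toy_data(self):
        rng = np.random.default_rng(0)
        x = np.zeros((32, 16, 16), dtype=np.float32)
        y = np.array([0, 1] * 16)
        x[y == 1, 4:8, 4:8] = 1.0
        x += (rng.random(x.shape) < 0.02)
        cfg = TrainConfig(epochs=30, batch_size=8, learning_rate=1e-3, seed=0)
        _, history = train_model(build_model(TOY, seed=0), x, y, x, y, cfg)
        assert history[-1]["train_loss"] < history[0]["train_loss"]
        assert history[-1]["val_auc"] > 0.9

    def test_gradients_match_finite_differences(self):
        """Analytic backprop vs central differences on the largest-magnitude
        entries of each weight array (float32 tolerance)."""
        bundle = build_model(TOY, seed=1)
        net = NumpyCnn(bundle)
        rng = np.random.default_rng(0)
        x = rng.random((3, 16, 16, 1)).astype(np.float32)
        y = np.eye(2, dtype=np.float32)[[0, 1, 1]]

        def loss():
            p, _ = net.forward(x)
            return float(-np.mean(np.log(p[np.arange(3), y.argmax(1)])))

        probs, cache = net.forward(x)
        grads = net.backward(probs, y, cache)
        eps = 5e-3
        for key in ("conv1_W", "conv2_W", "dense1_W", "out_W"):
            flat = net.weights[key].ravel()
            g = grads[key].ravel()
            for i in np.argsort(-np.abs(g))[:3]:
                orig = flat[i]
                flat[i] = orig + eps
                lp = loss()
                flat[i] = orig - eps
                lm = loss()
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(g[i], rel=0.05, abs=1e-4)


class TestSerialization:
    def test_round_trip_preserves_weights(self):
        bundle = build_model(TOY, seed=2)
        doc = export_json(bundle)
        text = json.dumps(doc)  # full JSON text round trip
        back = import_json(text)
        for k in bundle.weights:
            scale = np.abs(bundle.weights[k]).max() or 1.0
            assert np.abs(back.weights[k] - bundle.weights[k]).max() <= 1e-7 * scale

    def test_single_filter_kernel_shape_recorded(self):
        spec = CnnSpec(
            input_height=16, input_width=16, n_blocks=1, filters=1,
            dense1=2, dense2=2, dropout_rate=0.0,
        )
        doc = export_json(build_model(spec, seed=0))
        conv = next(l for l in doc["layers"] if l["type"] == "conv2d")
        assert conv["kernel_shape"] == [3, 3, 1, 1]

    def test_dropped_bias_rejected(self):
        doc = export_json(build_model(TOY, seed=0))
        del doc["layers"][0]["bias"]
        with pytest.raises(FormatError):
            import_json(doc)

    def test_unknown_layer_type_rejected(self):
        doc = export_json(build_model(TOY, seed=0))
        doc["layers"][0]["type"] = "transformer"
        with pytest.raises(FormatError):
            import_json(doc)

    def test_wrong_shape_rejected(self):
        doc = export_json(build_model(TOY, seed=0))
        doc["layers"][0]["kernel"] = [[[[0.0]]]]
        with pytest.raises(FormatError):
            import_json(doc)


class TestInference:
    def test_zero_weights_give_uniform_softmax(self):
        bundle = build_model(TOY, seed=0)
        for k in bundle.weights:
            bundle.weights[k][:] = 0.0
        doc = export_json(bundle)
        pred = infer(doc, _rand_images(1, 16, 16)[0])
        assert pred.p_af == pytest.approx(0.5, abs=1e-9)
        assert pred.p_nonaf == pytest.approx(0.5, abs=1e-9)

    def test_matches_brute_force_forward_on_toy_network(self):
        """Both engines agree with a loop-based oracle forward pass."""
        spec = CnnSpec(
            input_height=8, input_width=8, n_blocks=1, filters=2,
            dense1=3, dense2=2, dropout_rate=0.0,
        )
        bundle = build_model(spec, seed=5)
        rng = np.random.default_rng(2)
        img = (rng.random((8, 8)) < 0.3).astype(float)

        w = bundle.weights
        conv = np.zeros((8, 8, 2))
        pad = np.zeros((10, 10))
        pad[1:9, 1:9] = img
        for r in range(8):
            for c in range(8):
                for f in range(2):
                    acc = w["conv1_b"][f]
                    for i in range(3):
                        for j in range(3):
                            acc += pad[r + i, c + j] * w["conv1_W"][i, j, 0, f]
                    conv[r, c, f] = max(acc, 0.0)
        pooled = np.zeros((4, 4, 2))
        for r in range(4):
            for c in range(4):
                for f in range(2):
                    pooled[r, c, f] = conv[2 * r : 2 * r + 2, 2 * c : 2 * c + 2, f].max()
        h1 = np.maximum(pooled.reshape(-1) @ w["dense1_W"] + w["dense1_b"], 0)
        h2 = np.maximum(h1 @ w["dense2_W"] + w["dense2_b"], 0)
        logits = h2 @ w["out_W"] + w["out_b"]
        expected = np.exp(logits - logits.max())
        expected /= expected.sum()

        doc = export_json(bundle)
        edge = predict_proba(doc, [img])[0]
        framework = NumpyCnn(bundle).predict_proba(img[None])[0]
        np.testing.assert_allclose(edge, expected, atol=1e-7)
        np.testing.assert_allclose(framework, expected, atol=1e-5)

    def test_edge_matches_framework_on_random_images(self):
        bundle = build_model(CnnSpec(), seed=3)
        doc = export_json(bundle)
        x = _rand_images(10, seed=4)
        edge = predict_proba(doc, x)
        framework = NumpyCnn(bundle).predict_proba(x)
        assert np.max(np.abs(edge - framework)) < 1e-5

    def test_softmax_sums_to_one(self):
        bundle = build_model(TOY, seed=6)
        probs = NumpyCnn(bundle).predict_proba(_rand_images(5, 16, 16, seed=1))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_infer_is_pure(self):
        doc = export_json(build_model(TOY, seed=0))
        img = _rand_images(1, 16, 16)[0]
        a = infer(doc, img)
        b = infer(doc, img)
        assert a.p_af == b.p_af

    def test_shape_mismatch_rejected(self):
        doc = export_json(build_model(TOY, seed=0))
        with pytest.raises(Exception):
            infer(doc, np.zeros((32, 32)))

    def test_prediction_label_cutoff(self):
        p = Prediction(p_nonaf=0.6, p_af=0.4, cutoff=0.4)
        assert p.label == 1  # score equal to the cutoff predicts positive
        assert Prediction(p_nonaf=0.6, p_af=0.4, cutoff=0.5).label == 0
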