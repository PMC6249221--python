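"""CNN family: architecture audit, gradients, training behavior, features."""

import numpy as np
import pytest
from scipy.signal import correlate

import shockadvice.cnn as C
from shockadvice import (
    ChannelStack,
    CnnConfig,
    build_cnne,
    extract_features,
    forward_shapes,
    predict_fcnn,
    train_cnne,
)
from shockadvice.cnn import count_parameters, flatten_width, load_model, save_model


def toy_dataset(n=40, length=400, seed=0):
    """Two classes separated by dominant frequency, 3 identical channels."""
    t = np.arange(length) / 250.0
    xs, ys = [], []
    for i in range(n):
        r = np.random.default_rng(seed * 10_000 + i)
        lab = i % 2
        f = 4.0 if lab else 12.0
        sig = np.sin(2 * np.pi * f * t + r.uniform(0, 2 * np.pi))
        sig = sig + 0.1 * r.normal(size=length)
        xs.append(np.tile(sig, (3, 1)))
        ys.append(lab)
    return np.asarray(xs, dtype=np.float32), np.asarray(ys)


TOY_CFG = dict(input_len=400, n_channels=3, epochs=6, batch_size=16)


class TestArchitecture:
    def test_selected_network_shape_trace(self):
        trace = forward_shapes(CnnConfig(ns=3, nd=1))
        lengths = {name: ln for name, ln, _ in trace}
        assert lengths["conv1.1"] == 2000
        assert (lengths["pool1"], lengths["pool2"], lengths["pool3"]) == (995, 493, 242)
        assert flatten_width(CnnConfig(ns=3, nd=1)) == 9680

    def test_selected_network_layer_for_layer(self):
        model = build_cnne(CnnConfig(ns=3, nd=1))
        convs = [l for l in model.layers if isinstance(l, C._Conv1d)]
        assert [c.w.shape[0] for c in convs] == [10, 20, 40]
        assert all(c.w.shape[2] == 101 for c in convs)
        assert (C.PAD, C.POOL_K, C.POOL_S) == (50, 11, 2)
        pools = [l for l in model.layers if isinstance(l, C._MaxPool)]
        assert len(pools) == 3
        dense = [l for l in model.layers if isinstance(l, C._Dense)]
        assert dense[0].w.shape == (100, 9680)
        assert dense[1].w.shape == (2, 100)
        assert model.layer_summary()[-4:] == ["Dense", "ReLU", "Dropout", "Dense"]

    def test_minimal_config_structure(self):
        model = build_cnne(CnnConfig(ns=1, nd=1))
        assert model.layer_summary() == [
            "Conv1d", "ReLU", "MaxPool", "Flatten", "Dense", "ReLU", "Dropout",
            "Dense",
        ]

    def test_parameter_count_monotone_in_depth_and_sections(self):
        base = count_parameters(CnnConfig(ns=2, nd=1, input_len=400))
        assert count_parameters(CnnConfig(ns=2, nd=2, input_len=400)) > base
        assert count_parameters(CnnConfig(ns=3, nd=1, input_len=400)) > base

    def test_collapsing_temporal_length_rejected(self):
        with pytest.raises(ValueError):
            CnnConfig(ns=8, nd=1, input_len=100)


class TestConvCorrectness:
    def test_forward_matches_direct_correlation(self, rng):
        conv = C._Conv1d(2, 3, rng, np.float64)
        x = rng.normal(size=(2, 2, 60))
        y = conv.forward(x, train=False)
        xp = np.pad(x, ((0, 0), (0, 0), (C.PAD, C.PAD)))
        for b in range(2):
            for f in range(3):
                direct = sum(
                    correlate(xp[b, c], conv.w[f, c], mode="valid") for c in range(2)
                ) + conv.b[f]
                np.testing.assert_allclose(y[b, f], direct, atol=1e-10)

    def test_backprop_matches_numeric_gradients(self, rng):
        cfg = CnnConfig(ns=1, nd=1, input_len=120, n_channels=2, fc_width=5,
                        dropout=0.0, momentum=0.0)
        model = build_cnne(cfg, seed=1, dtype=np.float64)
        x = rng.normal(size=(3, 2, 120))
        y = np.array([0, 1, 0])

        def loss():
            p = C._softmax(model.forward(x.copy(), train=False))
            return float(-np.log(p[np.arange(3), y]).mean())

        logits = model.forward(x.copy(), train=True)
        d = C._softmax(logits)
        d[np.arange(3), y] -= 1
        g = d / 3
        for layer in reversed(model.layers):
            g = layer.backward(g)

        for layer in model.layers:
            for (_, par), grad in zip(layer.params(), layer.grads()):
                flat, gflat = par.ravel(), grad.ravel()
                for i in rng.choice(flat.size, size=min(5, flat.size), replace=False):
                    orig, eps = flat[i], 1e-6
                    flat[i] = orig + eps
                    lp = loss()
                    flat[i] = orig - eps
                    lm = loss()
                    flat[i] = orig
                    num = (lp - lm) / (2 * eps)
                    assert abs(num - gflat[i]) <= 1e-5 * (1 + abs(num))


class TestTraining:
    def test_learns_separable_toy_problem(self):
        x, y = toy_dataset()
        cfg = CnnConfig(ns=2, nd=1, lr=0.005, momentum=0.9, dropout=0.1, **TOY_CFG)
        model = train_cnne(build_cnne(cfg, seed=2), (x, y), seed=5)
        labels, probs = predict_fcnn(model, x)
        assert (labels == y).mean() >= 0.9
        assert model.loss_log[-1] < model.loss_log[0]

    def test_zero_learning_rate_leaves_weights_unchanged(self):
        x, y = toy_dataset(n=8)
        cfg = CnnConfig(ns=1, nd=1, lr=0.0, momentum=0.9, dropout=0.1, **TOY_CFG)
        model = build_cnne(cfg, seed=3)
        before = [p.copy() for l in model.layers for _, p in l.params()]
        train_cnne(model, (x, y), epochs=2, seed=0)
        after = [p for l in model.layers for _, p in l.params()]
        for b, a in zip(before, after):
            np.testing.assert_array_equal(b, a)

    def test_training_is_deterministic_given_seed(self):
        x, y = toy_dataset(n=16)
        cfg = CnnConfig(ns=1, nd=1, lr=0.01, momentum=0.5, dropout=0.2, **TOY_CFG)
        m1 = train_cnne(build_cnne(cfg, seed=4), (x, y), epochs=3, seed=7)
        m2 = train_cnne(build_cnne(cfg, seed=4), (x, y), epochs=3, seed=7)
        assert m1.loss_log == m2.loss_log

    def test_single_class_data_rejected(self):
        x, _ = toy_dataset(n=8)
        y = np.zeros(8, dtype=int)
        cfg = CnnConfig(ns=1, nd=1, **TOY_CFG)
        with pytest.raises(ValueError):
            train_cnne(build_cnne(cfg), (x, y))

    def test_shape_mismatch_rejected(self):
        cfg = CnnConfig(ns=1, nd=1, **TOY_CFG)
        with pytest.raises(ValueError):
            train_cnne(build_cnne(cfg), (np.zeros((4, 3, 99)), np.array([0, 1, 0, 1])))


class TestFeaturesAndPrediction:
    def test_feature_vector_length_is_fc_width(self):
        model = build_cnne(CnnConfig(ns=1, nd=1, input_len=400))
        stack = ChannelStack(pecg=np.zeros(400), sh_signal=np.zeros(400),
                             nsh_signal=np.zeros(400), label=0)
        assert extract_features(model, stack).shape == (100,)

    def test_zero_input_features_equal_relu_of_fc_bias(self):
        model = build_cnne(CnnConfig(ns=1, nd=1, input_len=400), seed=0)
        fc1 = [l for l in model.layers if isinstance(l, C._Dense)][0]
        fc1.b[:] = np.random.default_rng(0).normal(size=fc1.b.shape)
        stack = ChannelStack(pecg=np.zeros(400), sh_signal=np.zeros(400),
                             nsh_signal=np.zeros(400), label=0)
        np.testing.assert_allclose(extract_features(model, stack),
                                   np.maximum(fc1.b, 0), atol=1e-6)

    def test_inference_is_pure(self):
        x, y = toy_dataset(n=8)
        cfg = CnnConfig(ns=1, nd=1, dropout=0.3, **TOY_CFG)
        model = train_cnne(build_cnne(cfg, seed=1), (x, y), epochs=1, seed=1)
        f1 = extract_features(model, x[0])
        f2 = extract_features(model, x[0])
        np.testing.assert_array_equal(f1, f2)

    def test_softmax_probabilities_normalized(self):
        model = build_cnne(CnnConfig(ns=1, nd=1, input_len=400))
        x = np.random.default_rng(0).normal(size=(5, 3, 400)).astype(np.float32)
        labels, probs = predict_fcnn(model, x)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert set(np.unique(labels)) <= {0, 1}


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        x, y = toy_dataset(n=8)
        cfg = CnnConfig(ns=1, nd=1, **TOY_CFG)
        model = train_cnne(build_cnne(cfg, seed=6), (x, y), epochs=1, seed=2)
        save_model(model, tmp_path / "m.npz")
        loaded = load_model(tmp_path / "m.npz")
        np.testing.assert_array_equal(extract_features(model, x[0]),
                                      extract_features(loaded, x[0]))
        assert loaded.loss_log == model.loss_log
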