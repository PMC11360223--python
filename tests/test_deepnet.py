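import numpy as np
import pytest

import nirgaf.deepnet as dn
from nirgaf.deepnet import (
    CNNClassifier,
    CoordinateAttention,
    TrainConfig,
    build_network,
    softmax,
    train,
)

EXPECTED_CHAIN = [
    ("conv1", (64, 64, 32)),
    ("relu", (64, 64, 32)),
    ("conv2", (64, 64, 32)),
    ("relu", (64, 64, 32)),
    ("maxpool", (32, 32, 32)),
    ("conv3", (32, 32, 64)),
    ("relu", (32, 32, 64)),
    ("maxpool", (16, 16, 64)),
    ("conv4", (16, 16, 128)),
    ("relu", (16, 16, 128)),
    ("maxpool", (8, 8, 128)),
    ("globalmaxpool", (128,)),
    ("dense1", (128,)),
    ("relu", (128,)),
    ("dropout", (128,)),
    ("dense2", (2,)),
]


def _separable_images(n=64, seed=0):
    rng = np.random.default_rng(seed)
    imgs = 0.1 * rng.random((n, 64, 64))
    y = np.array(["A"] * (n // 2) + ["B"] * (n // 2))
    imgs[n // 2 :, 16:48, 16:48] += 0.7
    return imgs.astype(np.float32), y


class TestArchitecture:
    def test_shape_chain_matches_reference_table(self):
        chain = build_network(seed=0).shape_chain()
        assert chain == EXPECTED_CHAIN

    def test_cacnn_inserts_attention_after_conv1(self):
        chain = build_network(use_ca=True, seed=0).shape_chain()
        idx = [name for name, _ in chain].index("coordatt")
        assert chain[idx] == ("coordatt", (64, 64, 32))
        assert chain[idx - 2][0] == "conv1" and chain[idx + 1][0] == "conv2"

    def test_parameter_count_difference_is_exactly_ca(self):
        cnn = build_network(seed=0)
        cacnn = build_network(use_ca=True, ca_reduction=8, seed=0)
        c, c_mid = 32, max(32 // 8, 8)
        ca_params = (c * c_mid + c_mid) + 2 * (c_mid * c + c)
        assert cacnn.n_parameters - cnn.n_parameters == ca_params

    def test_wrong_input_size_rejected(self):
        net = build_network(seed=0)
        with pytest.raises(ValueError, match="64x64"):
            net.forward(np.zeros((1, 32, 32, 1)))

    def test_pinned_gates_equal_plain_cnn_forward(self, rng):
        """Architectural-equivalence oracle: CA with unit gates is the identity."""
        cnn = build_network(seed=0)
        cacnn = build_network(use_ca=True, pin_ca_gates=True, seed=1)
        donors = [l for l in cnn.layers if l.params]
        receivers = [l for l in cacnn.layers if l.params and l.name != "coordatt"]
        for src, dst in zip(donors, receivers):
            for k in src.params:
                dst.params[k] = src.params[k].copy()
        x = rng.random((3, 64, 64, 1)).astype(np.float32)
        np.testing.assert_allclose(
            cacnn.forward(x), cnn.forward(x), rtol=1e-5, atol=1e-6
        )


class TestCoordinateAttention:
    def test_output_shape_preserved(self, rng):
        ca = CoordinateAttention(16, 8, np.random.default_rng(0))
        x = rng.random((2, 12, 10, 16)).astype(np.float32)
        assert ca.forward(x).shape == x.shape

    def test_gate_values_in_unit_interval(self, rng):
        ca = CoordinateAttention(16, 8, np.random.default_rng(0))
        gh, gw = ca.gates(rng.random((2, 8, 8, 16)).astype(np.float32))
        for g in (gh, gw):
            assert np.all(g > 0) and np.all(g < 1)

    def test_constant_input_gives_constant_gates(self):
        ca = CoordinateAttention(8, 8, np.random.default_rng(2))
        x = np.ones((1, 6, 9, 8), dtype=np.float32) * np.arange(1, 9, dtype=np.float32)
        gh, gw = ca.gates(x)
        assert np.max(np.abs(gh - gh[:, :1, :])) < 1e-7
        assert np.max(np.abs(gw - gw[:, :1, :])) < 1e-7

    def test_invalid_reduction(self):
        with pytest.raises(ValueError, match="reduction"):
            CoordinateAttention(16, 0, np.random.default_rng(0))


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Analytic gradients of every layer agree with central differences."""
        old = dn.DTYPE
        dn.DTYPE = np.float64
        try:
            net = build_network(
                n_classes=2, use_ca=True, dropout=0.0, seed=1, input_size=8
            )
            for layer, key in net.parameters():
                layer.params[key] = layer.params[key].astype(np.float64)
            rng = np.random.default_rng(0)
            x = rng.random((3, 8, 8, 1))
            y = np.eye(2)[rng.integers(0, 2, 3)]

            def loss():
                p = softmax(net.forward(x))
                return -np.mean(np.sum(y * np.log(p + 1e-12), axis=1))

            p = softmax(net.forward(x))
            net.backward((p - y) / 3)
            for layer, key in net.parameters():
                flat = layer.params[key].ravel()
                g = layer.grads[key].ravel()
                for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                    orig = flat[i]
                    flat[i] = orig + 1e-6
                    lp = loss()
                    flat[i] = orig - 1e-6
                    lm = loss()
                    flat[i] = orig
                    num = (lp - lm) / 2e-6
                    assert abs(num - g[i]) < 1e-4 * max(1.0, abs(num) + abs(g[i])), (
                        layer.name,
                        key,
                    )
        finally:
            dn.DTYPE = old


class TestTraining:
    def test_lr_schedule_halves_every_200(self):
        cfg = TrainConfig()
        assert cfg.lr_at(0) == pytest.approx(5e-4)
        assert cfg.lr_at(200) == pytest.approx(2.5e-4)
        assert cfg.lr_at(400) == pytest.approx(1.25e-4)

    def test_learns_separable_images(self):
        imgs, y = _separable_images()
        clf = CNNClassifier(
            config=TrainConfig(total_iterations=40, batch_size=16), seed=0
        )
        clf.fit(imgs, y)
        assert np.mean(clf.predict(imgs) == y) >= 0.95

    def test_dropout_changes_training_trajectory(self):
        imgs, y = _separable_images(n=16)
        onehot = np.stack([(y == c).astype(np.float32) for c in np.unique(y)], axis=1)
        hists = []
        for rate in (0.0, 0.25):
            net = build_network(dropout=rate, seed=0)
            hists.append(
                train(net, imgs, onehot, TrainConfig(total_iterations=6, batch_size=8))
            )
        assert hists[0]["loss"] != hists[1]["loss"]

    def test_history_records_every_iteration(self):
        imgs, y = _separable_images(n=8)
        clf = CNNClassifier(config=TrainConfig(total_iterations=5, batch_size=4), seed=0)
        clf.fit(imgs, y)
        assert len(clf.history_["loss"]) == 5
        assert clf.history_["lr"] == [5e-4] * 5

    def test_reproducible_with_fixed_seed(self):
        imgs, y = _separable_images(n=8)
        preds = []
        for _ in range(2):
            clf = CNNClassifier(
                config=TrainConfig(total_iterations=5, batch_size=4), seed=9
            )
            clf.fit(imgs, y)
            preds.append(clf.predict_proba(imgs))
        np.testing.assert_array_equal(preds[0], preds[1])


class TestPredictProba:
    def test_rows_sum_to_one_and_argmax_consistency(self):
        imgs, y = _separable_images(n=8)
        clf = CNNClassifier(config=TrainConfig(total_iterations=3, batch_size=4), seed=0)
        clf.fit(imgs, y)
        probs = clf.predict_proba(imgs)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs >= 0)
        np.testing.assert_array_equal(
            clf.predict(imgs), clf.class_order_[probs.argmax(axis=1)]
        )

    def test_zero_logits_give_uniform(self):
        assert softmax(np.zeros((1, 2)))[0] == pytest.approx([0.5, 0.5])
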