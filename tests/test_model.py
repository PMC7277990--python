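"""Architecture structure, layer gradients and training behaviour."""

import numpy as np
import pytest

from spermhead import nn
from spermhead.model import (SMALL_ARCHITECTURE, ArchitectureConfig,
                             SpermHeadCNNClassifier, TrainingConfig, build_model,
                             count_conv_layers, train)
from spermhead.nn import BatchNorm, Conv2d, Dense, LeakyReLU


@pytest.fixture(scope="module")
def default_net():
    return build_model(ArchitectureConfig(), (35, 35, 3), seed=0)


class TestStructure:
    def test_default_build_has_53_convolutions(self, default_net):
        assert count_conv_layers(default_net) == 53
        assert default_net.conv_layers_per_component() == [9, 12, 18, 9]

    def test_conv_count_formula_for_any_repetitions(self):
        for reps in [(1, 1, 1, 1), (3, 4, 6, 3), (2, 2), (5,)]:
            cfg = ArchitectureConfig(repetitions=reps)
            assert cfg.conv_layer_count == 1 + 3 * sum(reps) + len(reps)
        net = build_model(ArchitectureConfig(repetitions=(1, 1, 1, 1)), (35, 35, 3))
        assert count_conv_layers(net) == 17

    def test_single_conv_toy_counts_one(self):
        rng = np.random.default_rng(0)
        layers = [Conv2d(3, 4, 3, rng)]
        assert sum(isinstance(ly, Conv2d) for ly in layers) == 1

    def test_block_filter_counts_and_kernel_sizes(self, default_net):
        for blocks in default_net.components:
            for blk in blocks:
                assert blk.conv1.out_channels == 128 and blk.conv1.kernel_size == 1
                assert blk.conv5.out_channels == 32 and blk.conv5.kernel_size == 5
                assert blk.conv3.out_channels == 32 and blk.conv3.kernel_size == 3

    def test_transitions_halve_channels(self, default_net):
        for tr in default_net.transitions:
            assert tr.conv.out_channels == tr.conv.in_channels // 2

    def test_channel_growth_trace(self, default_net):
        assert default_net.channel_trace == [64, 160, 80, 208, 104, 296, 148, 244, 122]

    def test_every_conv_is_preceded_by_batchnorm_and_leakyrelu(self, default_net):
        # stem
        assert isinstance(default_net.stem_bn, BatchNorm)
        assert isinstance(default_net.stem_act, LeakyReLU)
        for blocks, tr in zip(default_net.components, default_net.transitions):
            for blk in blocks:
                # bottleneck conv consumes act1(bn1(x)); both branch convs
                # consume the shared act2(bn2(bottleneck))
                assert isinstance(blk.bn1, BatchNorm) and isinstance(blk.act1, LeakyReLU)
                assert isinstance(blk.bn2, BatchNorm) and isinstance(blk.act2, LeakyReLU)
                assert blk.bn2.channels == blk.conv1.out_channels
            assert isinstance(tr.bn, BatchNorm) and isinstance(tr.act, LeakyReLU)

    def test_spatial_halving_schedule(self):
        net = build_model(ArchitectureConfig(**SMALL_ARCHITECTURE), (35, 35, 3))
        x = np.zeros((1, 35, 35, 3), dtype=np.float32)
        z = net.stem_act.forward(net.stem_bn.forward(x, False), False)
        z = net.stem.forward(z, False)
        sizes = []
        for blocks, tr in zip(net.components, net.transitions):
            for blk in blocks:
                z = blk.forward(z, False)
            z = tr.forward(z, False)
            sizes.append(z.shape[1])
        assert sizes == [17, 8, 4, 2]

    def test_undersized_input_rejected(self):
        with pytest.raises(ValueError):
            build_model(ArchitectureConfig(), (8, 8, 3))

    @pytest.mark.parametrize("bad", [
        dict(bottleneck_filters=0), dict(transition_ratio=0.0),
        dict(l2_lambda=-1.0), dict(repetitions=()),
    ])
    def test_invalid_architecture_rejected(self, bad):
        with pytest.raises(ValueError):
            ArchitectureConfig(**bad)


def numeric_grad(f, arr, idx, eps=1e-5):
    orig = arr[idx]
    arr[idx] = orig + eps
    up = f()
    arr[idx] = orig - eps
    down = f()
    arr[idx] = orig
    return (up - down) / (2 * eps)


class TestLayerGradients:
    """Central-difference checks of the hand-written backward passes."""

    @pytest.fixture(autouse=True)
    def float64_engine(self, monkeypatch):
        monkeypatch.setattr(nn, "DTYPE", np.float64)

    def check_layer(self, layer, x, params_to_check=("W", "b")):
        rng = np.random.default_rng(1)
        r = rng.normal(size=layer.forward(x, True).shape)

        def loss():
            return float((layer.forward(x, True) * r).sum())

        layer.forward(x, True)
        dx = layer.backward(r.astype(x.dtype))
        idxs = [tuple(rng.integers(0, s) for s in x.shape) for _ in range(5)]
        for idx in idxs:
            assert dx[idx] == pytest.approx(numeric_grad(loss, x, idx), rel=1e-4, abs=1e-7)
        for name in params_to_check:
            if name not in layer.params:
                continue
            p = layer.params[name]
            layer.forward(x, True)
            layer.backward(r.astype(x.dtype))
            g = layer.grads[name]
            for _ in range(5):
                idx = tuple(rng.integers(0, s) for s in p.shape)
                assert g[idx] == pytest.approx(numeric_grad(loss, p, idx),
                                               rel=1e-4, abs=1e-7)

    def test_conv2d_backward(self):
        rng = np.random.default_rng(0)
        layer = Conv2d(3, 4, 3, rng)
        self.check_layer(layer, rng.normal(size=(2, 7, 7, 3)))

    def test_batchnorm_backward(self):
        rng = np.random.default_rng(0)
        layer = BatchNorm(3)
        self.check_layer(layer, rng.normal(size=(4, 5, 5, 3)),
                         params_to_check=("gamma", "beta"))

    def test_dense_backward_including_l2(self):
        rng = np.random.default_rng(0)
        layer = Dense(6, 3, rng, l2=0.01)
        x = rng.normal(size=(4, 6))
        r = rng.normal(size=(4, 3))

        def loss():
            return float((layer.forward(x, True) * r).sum()) + layer.l2_penalty()

        layer.forward(x, True)
        layer.backward(r)
        g = layer.grads["W"]
        for _ in range(5):
            idx = tuple(rng.integers(0, s) for s in layer.params["W"].shape)
            assert g[idx] == pytest.approx(numeric_grad(loss, layer.params["W"], idx),
                                           rel=1e-4, abs=1e-7)

    def test_whole_net_gradient_on_tiny_model(self):
        from spermhead.nn import softmax_cross_entropy
        cfg = ArchitectureConfig(stem_filters=4, bottleneck_filters=5,
                                 branch_filters=3, repetitions=(1,),
                                 num_classes=3, l2_lambda=0.0)
        net = build_model(cfg, (16, 16, 3), seed=0)
        rng = np.random.default_rng(2)
        x = rng.normal(size=(2, 16, 16, 3))
        onehot = np.eye(3)[[0, 2]].astype(np.float64)

        def loss():
            return softmax_cross_entropy(net.forward(x, True), onehot)[0]

        _, dlogits = softmax_cross_entropy(net.forward(x, True), onehot)
        net.backward(dlogits)
        w = net.dense.params["W"]
        gw = net.dense.grads["W"].copy()
        sw = net.stem.params["W"]
        gs = net.stem.grads["W"].copy()
        for _ in range(3):
            idx = tuple(rng.integers(0, s) for s in w.shape)
            assert gw[idx] == pytest.approx(numeric_grad(loss, w, idx),
                                            rel=1e-3, abs=1e-8)
            idx = tuple(rng.integers(0, s) for s in sw.shape)
            assert gs[idx] == pytest.approx(numeric_grad(loss, sw, idx),
                                            rel=1e-3, abs=1e-8)


class TestTraining:
    @staticmethod
    def tiny_fit(epochs=3, n=12, dev=True, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.random((n, 16, 16, 3), dtype=np.float32)
        y = np.array(["a", "b"] * (n // 2))
        clf = SpermHeadCNNClassifier(
            stem_filters=4, bottleneck_filters=4, branch_filters=2,
            repetitions=(1, 1), learning_rate=1e-3, decay=0.0, batch_size=4,
            epochs=epochs, random_state=seed)
        devset = (x[:4], y[:4]) if dev else None
        return clf.fit(x, y, dev=devset)

    def test_history_length_and_best_epoch_range(self):
        clf = self.tiny_fit(epochs=3)
        assert len(clf.history_) == 3
        assert clf.best_epoch_ in (1, 2, 3)

    def test_best_epoch_is_argmin_of_dev_loss(self):
        clf = self.tiny_fit(epochs=4)
        losses = [h["dev_loss"] for h in clf.history_]
        assert clf.best_epoch_ == int(np.argmin(losses)) + 1

    def test_predict_proba_rows_sum_to_one(self):
        clf = self.tiny_fit(epochs=1)
        rng = np.random.default_rng(3)
        x = rng.random((7, 16, 16, 3), dtype=np.float32)
        p = clf.predict_proba(x)
        assert p.shape == (7, 2)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-5)

    def test_duplicated_inputs_get_identical_outputs(self):
        clf = self.tiny_fit(epochs=1)
        x = np.random.default_rng(4).random((3, 16, 16, 3), dtype=np.float32)
        p = clf.predict_proba(np.concatenate([x, x]))
        np.testing.assert_array_equal(p[:3], p[3:])

    def test_label_width_mismatch_rejected(self):
        cfg = ArchitectureConfig(stem_filters=4, bottleneck_filters=4,
                                 branch_filters=2, repetitions=(1, 1),
                                 num_classes=3)
        net = build_model(cfg, (16, 16, 3))
        x = np.zeros((4, 16, 16, 3), dtype=np.float32)
        onehot = np.eye(2)[[0, 1, 0, 1]].astype(np.float32)
        with pytest.raises(ValueError, match="num_classes"):
            train(net, (x, onehot), None, TrainingConfig(batch_size=4, epochs=1))

    def test_memorizes_small_set(self):
        """The scaled-down model drives training loss below 0.1 on 64
        memorization images within 30 epochs."""
        rng = np.random.default_rng(0)
        x = rng.random((64, 16, 16, 3), dtype=np.float32)
        y = rng.integers(0, 5, 64).astype(str)
        # l2_lambda=0: this probes raw optimization capacity, and the
        # recorded loss would otherwise include the dense weight penalty
        clf = SpermHeadCNNClassifier(**SMALL_ARCHITECTURE, l2_lambda=0.0,
                                     learning_rate=3e-3, decay=0.0,
                                     batch_size=16, epochs=30,
                                     random_state=0).fit(x, y)
        assert min(h["train_loss"] for h in clf.history_) < 0.1

    def test_learns_separable_two_class_set(self):
        """Normal-vs-Small synthetic heads: nearest-centroid on shape
        features is the separability oracle; the CNN must exceed it."""
        from sklearn.neighbors import NearestCentroid
        from spermhead.synthetic_data import (SyntheticDatasetConfig,
                                              generate_dataset, shape_features)
        cfg = SyntheticDatasetConfig(class_counts={"Normal": 200, "Small": 200},
                                     seed=5)
        x, y = generate_dataset(cfg).arrays()
        feats = np.array([shape_features(im) for im in x])
        z = (feats - feats.mean(0)) / feats.std(0)
        oracle = (NearestCentroid().fit(z, y).predict(z) == y).mean()
        assert oracle > 0.9
        clf = SpermHeadCNNClassifier(**SMALL_ARCHITECTURE, learning_rate=1e-3,
                                     decay=0.0, batch_size=32, epochs=8,
                                     random_state=1).fit(x, y)
        assert clf.history_[-1]["train_acc"] > 0.95


class TestAdam:
    def test_inverse_time_decay_schedule(self):
        rng = np.random.default_rng(0)
        layer = Dense(2, 2, rng)
        opt = nn.Adam([layer], lr=0.1, decay=0.5)
        layer.grads = {k: np.zeros_like(v) for k, v in layer.params.items()}
        assert opt.current_lr == pytest.approx(0.1)
        opt.step()
        assert opt.current_lr == pytest.approx(0.1 / 1.5)
        opt.step()
        assert opt.current_lr == pytest.approx(0.1 / 2.0)

    def test_sklearn_param_roundtrip(self):
        clf = SpermHeadCNNClassifier(epochs=3, branch_filters=8)
        params = clf.get_params()
        clone = SpermHeadCNNClassifier(**params)
        assert clone.get_params() == params
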