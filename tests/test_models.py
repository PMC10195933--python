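"""Network construction, training mechanics, and the estimator API."""

import numpy as np
import pytest

from mammoqa import nn
from mammoqa import models as mm
from mammoqa.models import (
    LandmarkRegressor, ModelConfig, PositioningClassifier, augment,
    build_network, class_weights, encode_landmark, predict_class,
    predict_landmark, scaled_down_config, select_epoch, split_train_val,
    train_network, TrainedModel,
)
from mammoqa.preprocess import TransformLog


def tiny_config(task="classification", **kw):
    """Smallest legal config: 32 px input, minimal width, for fast tests."""
    base = dict(task=task, input_side_px=32, width_multiplier=0.02,
                epochs=2, lr=0.01, momentum=0.9, seed=0)
    base.update(kw)
    return ModelConfig(**base)


class TestArchitecture:
    @pytest.mark.parametrize("task,head_cls", [
        ("classification", nn.SoftmaxCrossEntropy),
        ("regression", nn.SigmoidMSE),
    ])
    def test_layer_counts_and_heads(self, task, head_cls):
        cfg = ModelConfig(task=task, input_side_px=96, width_multiplier=0.05,
                          seed=0)
        net = build_network(cfg)
        convs = [l for l in net.layers if isinstance(l, nn.Conv3x3)]
        pools = [l for l in net.layers if isinstance(l, nn.MaxPool2x2)]
        bns = [l for l in net.layers if isinstance(l, nn.BatchNorm2d)]
        dense = [l for l in net.layers if isinstance(l, nn.Dense)]
        drops = [l for l in net.layers if isinstance(l, nn.Dropout)]
        assert len(convs) == 13
        assert all(c.kernel_size == (3, 3) for c in convs)
        assert len(pools) == 5
        assert len(bns) == 13          # batch norm after every conv
        assert len(dense) == 3         # two hidden ReLU layers + output head
        assert len(drops) == 1 and drops[0].p == 0.5
        assert isinstance(net.head, head_cls)
        # canonical 2-2-3-3-3 grouping: pools sit after convs 2, 4, 7, 10, 13
        seen_convs, pool_positions = 0, []
        for layer in net.layers:
            if isinstance(layer, nn.Conv3x3):
                seen_convs += 1
            if isinstance(layer, nn.MaxPool2x2):
                pool_positions.append(seen_convs)
        assert pool_positions == [2, 4, 7, 10, 13]

    def test_defaults_reproduce_training_recipe(self):
        cfg = ModelConfig()
        assert cfg.input_side_px == 224
        assert cfg.conv_layers == 13 and cfg.pool_layers == 5
        assert cfg.kernel == (3, 3) and cfg.dense_layers == 2
        assert cfg.dropout == 0.5
        assert cfg.lr == 1.0e-5 and cfg.batch_size == 32 and cfg.epochs == 160
        assert cfg.val_fraction == 0.25

    def test_scaled_down_forward_pass_is_finite(self):
        cfg = ModelConfig(task="classification", input_side_px=96,
                          width_multiplier=0.25, seed=1)
        net = build_network(cfg)
        out = net.predict(np.random.default_rng(0)
                          .random((2, 96, 96, 1)).astype(np.float32))
        assert out.shape == (2, 2)
        assert np.all(np.isfinite(out))
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-6)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(input_side_px=100).validate()   # not divisible by 32
        with pytest.raises(ValueError):
            ModelConfig(width_multiplier=0).validate()
        with pytest.raises(ValueError):
            ModelConfig(conv_layers=10).validate()
        with pytest.raises(ValueError):
            ModelConfig(task="segmentation").validate()


class TestClassWeights:
    def test_inverse_frequency(self):
        labels = [0] * 90 + [1] * 10
        w = class_weights(labels)
        assert w[1] == pytest.approx(5.0)
        assert w[0] == pytest.approx(100 / 180)

    def test_balanced_gives_unit_weights(self):
        w = class_weights([0] * 50 + [1] * 50)
        assert w == {0: 1.0, 1: 1.0}

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            class_weights([])
        with pytest.raises(ValueError):
            class_weights([1, 1, 1])

    def test_weighted_loss_of_balanced_batch_equals_unweighted(self):
        rng = np.random.default_rng(4)
        z = rng.normal(size=(8, 2)).astype(np.float32)
        y = np.array([0, 1] * 4)
        head = nn.SoftmaxCrossEntropy()
        w = class_weights(y)
        sw = np.array([w[int(c)] for c in y])
        l_w, _ = head.loss_grad(z, y, sw)
        l_u, _ = head.loss_grad(z, y, None)
        assert l_w == pytest.approx(l_u, rel=1e-6)


class TestAugment:
    def test_zero_ranges_identity(self):
        rng = np.random.default_rng(0)
        imgs = rng.random((3, 32, 32)).astype(np.float32)
        coords = rng.uniform(5, 25, (3, 2))
        out_i, out_c = augment(imgs, coords, 0, 0, 0, rng)
        np.testing.assert_array_equal(out_i, imgs)
        np.testing.assert_array_equal(out_c, coords)

    def test_deterministic_under_seed(self):
        imgs = np.random.default_rng(1).random((4, 32, 32)).astype(np.float32)
        a, _ = augment(imgs, None, 10, 0.05, 0.1, np.random.default_rng(7))
        b, _ = augment(imgs, None, 10, 0.05, 0.1, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    def test_coordinates_track_image_content(self):
        """A bright dot must end up where the transformed coords say."""
        side = 64
        rng = np.random.default_rng(5)
        for _ in range(10):
            r, c = rng.integers(20, 44, 2)
            img = np.zeros((1, side, side), dtype=np.float32)
            img[0, r, c] = 1.0
            coords = np.array([[float(c), float(r)]])  # (x, y)
            out, out_c = augment(img, coords, 15, 0.08, 0.15,
                                 np.random.default_rng(int(rng.integers(1e6))))
            peak = np.unravel_index(np.argmax(out[0]), out[0].shape)
            x, y = out_c[0]
            if 1 <= x <= side - 2 and 1 <= y <= side - 2:
                assert abs(peak[0] - y) <= 1.5
                assert abs(peak[1] - x) <= 1.5


class TestSplit:
    def test_three_to_one_proportion(self):
        X = np.arange(100)
        y = np.array([0, 1] * 50)
        Xt, Xv, yt, yv = split_train_val(X, y, 0.25, seed=3)
        assert len(Xt) == 75 and len(Xv) == 25
        assert set(Xt) | set(Xv) == set(range(100))
        assert not set(Xt) & set(Xv)

    def test_stratification_within_one_item(self):
        y = np.array([0] * 70 + [1] * 30)
        X = np.arange(100)
        _, _, yt, yv = split_train_val(X, y, 0.25, seed=1)
        assert abs(yv.sum() - 0.25 * 30) <= 1

    def test_deterministic(self):
        X = np.arange(40)
        y = np.array([0, 1] * 20)
        a = split_train_val(X, y, 0.25, seed=5)
        b = split_train_val(X, y, 0.25, seed=5)
        np.testing.assert_array_equal(a[0], b[0])


class TestCheckpointSelection:
    def test_argmax_accuracy(self):
        assert select_epoch([0.5, 0.9, 0.7], "accuracy") == 1

    def test_argmin_rmse(self):
        assert select_epoch([10, 8, 9], "rmse") == 1

    def test_tie_goes_to_earliest(self):
        assert select_epoch([0.9, 0.9, 0.8], "accuracy") == 0
        assert select_epoch([3.0, 3.0], "rmse") == 0


def _dot_dataset(n, side=32, seed=0):
    """Images with a bright blob; label = blob in left half; target = blob."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(0, 0.1, (n, side, side)).astype(np.float32)
    y = np.zeros(n, dtype=int)
    T = np.zeros((n, 2))
    yy, xx = np.mgrid[0:side, 0:side]
    for i in range(n):
        r, c = rng.integers(6, side - 6, 2)
        X[i] += np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / 8).astype(np.float32)
        y[i] = int(c < side // 2)
        T[i] = (c / side, r / side)
    return np.clip(X, 0, 1), y, T


class TestTraining:
    def test_loss_decreases_on_learnable_task(self):
        X, y, _ = _dot_dataset(48)
        cfg = tiny_config(epochs=5)
        net = build_network(cfg)
        tm = train_network(net, (X[:40], y[:40]), (X[40:], y[40:]), cfg)
        losses = tm.history["train_loss"].to_numpy()
        assert losses[-1] < losses[0]

    def test_selected_epoch_matches_history(self):
        X, y, _ = _dot_dataset(32, seed=1)
        cfg = tiny_config(epochs=3)
        tm = train_network(build_network(cfg), (X[:24], y[:24]),
                           (X[24:], y[24:]), cfg)
        accs = tm.history["val_accuracy"].to_numpy()
        assert tm.selected_epoch == int(np.argmax(accs))

    def test_training_is_deterministic(self):
        X, y, _ = _dot_dataset(24, seed=2)
        hists = []
        for _ in range(2):
            cfg = tiny_config(epochs=2)
            tm = train_network(build_network(cfg), (X[:18], y[:18]),
                               (X[18:], y[18:]), cfg)
            hists.append(tm.history)
        assert hists[0].equals(hists[1])

    def test_empty_sets_rejected(self):
        X, y, _ = _dot_dataset(8)
        cfg = tiny_config()
        with pytest.raises(ValueError):
            train_network(build_network(cfg), (X[:0], y[:0]), (X, y), cfg)


class TestPrediction:
    def _stub_model(self, u, side=96):
        cfg = scaled_down_config(seed=0)

        class StubNet:
            def predict(self, x, batch_size=64):
                return np.tile(np.asarray(u, dtype=float), (len(x), 1))

        import pandas as pd
        return TrainedModel(StubNet(), cfg, pd.DataFrame(), 0)

    def test_probabilities_sum_to_one(self):
        cfg = tiny_config()
        net = build_network(cfg)
        import pandas as pd
        tm = TrainedModel(net, cfg, pd.DataFrame(), 0)
        img = np.zeros((32, 32), dtype=np.float32)
        p = predict_class(tm, img)
        assert p.probabilities.sum() == pytest.approx(1.0, abs=1e-6)
        # pure function: identical output for duplicate input
        p2 = predict_class(tm, img)
        np.testing.assert_array_equal(p.probabilities, p2.probabilities)

    def test_landmark_scaling_convention(self):
        tm = self._stub_model((0.5, 0.5))
        log = TransformLog((1.0, 1.0))
        img = np.zeros((96, 96), dtype=np.float32)
        pt = predict_landmark(tm, img, log)
        np.testing.assert_allclose(pt, (48.0, 48.0))
        tm0 = self._stub_model((0.0, 0.0))
        np.testing.assert_allclose(predict_landmark(tm0, img, log), (0.0, 0.0))

    def test_missing_log_rejected(self):
        tm = self._stub_model((0.5, 0.5))
        with pytest.raises(ValueError):
            predict_landmark(tm, np.zeros((96, 96), dtype=np.float32), None)

    def test_encode_decode_round_trip(self):
        from mammoqa.preprocess import preprocess_for_model
        from mammoqa.phantom import PhantomParams, generate_phantom
        rec, gt = generate_phantom(PhantomParams(seed=13))
        _, log = preprocess_for_model(rec, side_px=96)
        u = encode_landmark(gt.nipple_xy_mm, log, 96)
        assert 0 <= u.min() and u.max() <= 1
        back = log.model_px_to_original_mm(u * 96)
        # round-trip within half an original-frame pixel (0.2 mm spacing)
        np.testing.assert_allclose(back, gt.nipple_xy_mm, atol=0.1)


class TestEstimators:
    def test_classifier_fit_predict_and_params(self):
        X, y, _ = _dot_dataset(32, seed=3)
        clf = PositioningClassifier(input_side_px=32, width_multiplier=0.02,
                                    epochs=2, lr=0.01, momentum=0.9, seed=0)
        assert clf.get_params()["epochs"] == 2
        clf.set_params(epochs=3)
        clf.fit(X, y)
        assert clf.selected_epoch_ < 3
        proba = clf.predict_proba(X[:4])
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert set(clf.predict(X[:4])) <= set(clf.classes_)

    def test_regressor_fit_predict(self):
        X, _, T = _dot_dataset(24, seed=4)
        reg = LandmarkRegressor(input_side_px=32, width_multiplier=0.02,
                                epochs=2, lr=0.01, momentum=0.9, seed=0)
        reg.fit(X, T)
        out = reg.predict(X[:3])
        assert out.shape == (3, 2)
        assert out.min() >= 0 and out.max() <= 1

    def test_regressor_rejects_bad_targets(self):
        X, _, T = _dot_dataset(8)
        reg = LandmarkRegressor(input_side_px=32, width_multiplier=0.02)
        with pytest.raises(ValueError):
            reg.fit(X, T[:, :1])
        with pytest.raises(ValueError):
            reg.fit(X, T * 5)


def test_save_load_round_trip(tmp_path):
    X, y, _ = _dot_dataset(16, seed=6)
    cfg = tiny_config(epochs=2)
    tm = train_network(build_network(cfg), (X[:12], y[:12]), (X[12:], y[12:]), cfg)
    path = tmp_path / "model.npz"
    mm.save_model(tm, path)
    tm2 = mm.load_model(path)
    assert tm2.config == tm.config
    assert tm2.selected_epoch == tm.selected_epoch
    x_in = X[:2][..., None]
    np.testing.assert_allclose(tm.network.predict(x_in),
                               tm2.network.predict(x_in), atol=1e-6)
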