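"""Reduced U-Net: architecture contracts, training behaviour, inference."""

import numpy as np
import pytest

from srscount.nn import Adam, bce_with_logits, sigmoid
from srscount.unet import (EarlyStopping, SegModelConfig, TrainConfig, UNet,
                           UNetSegmenter, build_model, expected_parameter_count,
                           train)

TINY = SegModelConfig(in_channels=2, kernels_per_level=(4, 8))


class TestArchitecture:
    def test_output_shape_and_range(self):
        m = UNet(TINY, seed=0)
        x = np.random.default_rng(0).random((2, 32, 32, 2)).astype(np.float32)
        p = sigmoid(m.forward(x, train=False))
        assert p.shape == (2, 32, 32, 1)
        assert np.all(p > 0) and np.all(p < 1)

    def test_parameter_count_matches_layer_sum_default(self):
        """Default architecture (2 in-channels, 16..256 kernels): the model's
        parameter total equals the independent closed-form layer sum."""
        cfg = SegModelConfig()
        # independent recomputation, written out layer by layer
        expected = 0
        chans = [2, 16, 32, 64, 128, 256]
        for i in range(5):  # encoder: two 3x3 convs per level
            expected += 9 * chans[i] * chans[i + 1] + chans[i + 1]
            expected += 9 * chans[i + 1] * chans[i + 1] + chans[i + 1]
        for c_deep, c in [(256, 128), (128, 64), (64, 32), (32, 16)]:
            expected += 4 * c_deep * c + c          # 2x2 up-conv
            expected += 9 * (2 * c) * c + c         # conv after concat
            expected += 9 * c * c + c
        expected += 16 + 1                          # 1x1 single-kernel head
        model = build_model(cfg)
        assert model.n_parameters == expected == expected_parameter_count(cfg)

    def test_indivisible_input_rejected(self):
        m = UNet(SegModelConfig(kernels_per_level=(4, 8, 16, 32, 64)), seed=0)
        x = np.zeros((1, 255, 255, 2), dtype=np.float32)
        with pytest.raises(ValueError, match="multiple of 16"):
            m.forward(x)

    def test_gradients_match_numerical(self):
        """Backprop agrees with central finite differences on a tiny net."""
        m = UNet(TINY, seed=1)
        rng = np.random.default_rng(1)
        x = rng.random((2, 8, 8, 2)).astype(np.float32)
        y = (rng.random((2, 8, 8, 1)) > 0.7).astype(np.float32)
        loss, d = bce_with_logits(m.forward(x), y)
        m.backward(d)
        params = m.parameters()
        for pi in (1, 5, len(params) - 1):
            p, g = params[pi]
            idx = tuple(0 for _ in p.shape)
            eps, old = 1e-3, p[idx].copy()
            p[idx] = old + eps
            lp = bce_with_logits(m.forward(x, train=False), y)[0]
            p[idx] = old - eps
            lm = bce_with_logits(m.forward(x, train=False), y)[0]
            p[idx] = old
            num = (lp - lm) / (2 * eps)
            assert abs(num - g[idx]) <= 1e-2 * max(1.0, abs(num))

    def test_checkpoint_round_trip(self, tmp_path):
        m = UNet(TINY, seed=3)
        x = np.random.default_rng(0).random((1, 16, 16, 2)).astype(np.float32)
        ref = m.forward(x, train=False)
        p = tmp_path / "model.npz"
        m.save(p)
        m2 = UNet.load(p)
        assert np.array_equal(m2.forward(x, train=False), ref)


class TestEarlyStopping:
    def test_monotone_increase_stops_at_one_plus_patience(self):
        """Validation loss rising from epoch 1 stops at epoch 1+patience."""
        stopper = EarlyStopping(patience=5)
        losses = [0.5 + 0.01 * e for e in range(100)]
        for epoch, loss in enumerate(losses, start=1):
            if stopper.update(epoch, loss):
                break
        assert epoch == 6 and stopper.best_epoch == 1

    def test_improvement_resets_counter(self):
        stopper = EarlyStopping(patience=3)
        seq = [1.0, 0.9, 0.95, 0.8, 0.85, 0.86, 0.87]
        stops = [stopper.update(e, v) for e, v in enumerate(seq, start=1)]
        assert stops == [False] * 6 + [True]
        assert stopper.best_epoch == 4


def _toy_data(n=10, size=16, seed=0, empty=False):
    rng = np.random.default_rng(seed)
    X = rng.random((n, size, size, 2)).astype(np.float32) * 0.2
    Y = np.zeros((n, size, size), dtype=np.float32)
    if not empty:
        # cells where the blue channel is boosted
        for i in range(n):
            r0, c0 = rng.integers(2, size - 6, 2)
            X[i, r0:r0 + 4, c0:c0 + 4, 1] += 0.7
            Y[i, r0:r0 + 4, c0:c0 + 4] = 1.0
    return X, Y


class TestTraining:
    def test_all_zero_masks_drive_probabilities_down(self):
        """Minimising cross-entropy against empty targets pushes the sigmoid
        output below 0.5 everywhere."""
        X, _ = _toy_data(n=12, empty=False)
        Y = np.zeros(X.shape[:3], dtype=np.float32)
        m = UNet(TINY, seed=0)
        cfg = TrainConfig(batch_size=4, max_epochs=30, patience_epochs=30, seed=0)
        m, _ = train(m, X, Y, cfg)
        probs = m.predict_proba_patches(X)
        assert probs.max() < 0.5

    def test_determinism(self):
        X, Y = _toy_data()
        runs = []
        for _ in range(2):
            m = UNet(TINY, seed=7)
            m, h = train(m, X, Y, TrainConfig(batch_size=4, max_epochs=3,
                                              patience_epochs=3, seed=7))
            runs.append((h.val_loss, m.get_weights()))
        assert runs[0][0] == runs[1][0]
        assert all(np.array_equal(a, b) for a, b in zip(runs[0][1], runs[1][1]))

    def test_history_best_epoch_is_argmin(self):
        X, Y = _toy_data(n=8)
        m = UNet(TINY, seed=2)
        m, h = train(m, X, Y, TrainConfig(batch_size=4, max_epochs=5,
                                          patience_epochs=5, seed=2))
        assert h.best_epoch == int(np.argmin(h.val_loss)) + 1
        assert h.epochs_run == len(h.val_loss) <= 5

    def test_nonbinary_masks_rejected(self):
        X, Y = _toy_data()
        with pytest.raises(ValueError, match="\\{0, 1\\}"):
            train(UNet(TINY, seed=0), X, Y + 0.5)

    def test_too_few_samples_rejected(self):
        X, Y = _toy_data(n=1)
        with pytest.raises(ValueError):
            train(UNet(TINY, seed=0), X, Y)


class _StubModel:
    """Constant-probability model for threshold-semantics tests."""

    def __init__(self, value):
        self.value = value
        self.config = SegModelConfig(in_channels=2, kernels_per_level=(4, 8))

    def predict_proba_patches(self, x, batch=8):
        return np.full(x.shape[:3], self.value, dtype=np.float32)


class TestPredict:
    def _stub_segmenter(self, value, patch_px=32):
        seg = UNetSegmenter(kernels_per_level=(4, 8), patch_px=patch_px)
        seg.model_ = _StubModel(value)
        return seg

    def test_probability_below_threshold_gives_empty_mask(self):
        seg = self._stub_segmenter(0.4)
        img = np.zeros((64, 64, 2), dtype=np.float32)
        assert seg.predict(img).sum() == 0

    def test_probability_exactly_half_is_noncell(self):
        """The cell rule is strictly greater-than 0.5."""
        seg = self._stub_segmenter(0.5)
        img = np.zeros((32, 32, 2), dtype=np.float32)
        assert seg.predict(img).sum() == 0

    def test_output_shape_matches_input_with_padding(self):
        seg = self._stub_segmenter(0.9, patch_px=32)
        img = np.zeros((50, 70, 2), dtype=np.float32)
        mask = seg.predict(img)
        assert mask.shape == (50, 70)
        assert mask.all()

    def test_wrong_channel_count_rejected(self):
        seg = self._stub_segmenter(0.9)
        with pytest.raises(ValueError, match="HxWx2"):
            seg.predict(np.zeros((32, 32, 3), dtype=np.float32))

    def test_sklearn_params_round_trip(self):
        seg = UNetSegmenter(kernels_per_level=(4, 8), max_epochs=2)
        params = seg.get_params()
        clone = UNetSegmenter(**params)
        assert clone.get_params() == params
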