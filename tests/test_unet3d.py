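"""U-Net architecture contracts, Dice loss values, training mechanics."""

import numpy as np
import pytest

from infarctseg import (
    UNetConfig,
    build_unet3d,
    dice_loss,
    divide_patches,
    load_model,
    predict_patches,
    save_model,
    train,
)
from infarctseg.errors import InputError, ParameterError, ShapeError
from infarctseg.patching import PatchSet


TINY = dict(depth=2, base_filters=2, dropout_rate=0.0, batch_size=2, patch_size=16, epochs=2)


class TestArchitecture:
    def test_output_two_channels_same_spatial_shape(self):
        model = build_unet3d(UNetConfig(**TINY))
        x = np.random.default_rng(0).random((16, 16, 16)).astype(np.float32)
        proba = model.predict_proba(x)
        assert proba.shape == (2, 16, 16, 16)

    def test_softmax_probabilities_sum_to_one(self):
        model = build_unet3d(UNetConfig(**TINY))
        x = np.random.default_rng(1).random((2, 16, 16, 16)).astype(np.float32)
        proba = model.predict_proba(x)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-5)

    def test_encoder_channels_double_per_level(self):
        cfg = UNetConfig(depth=3, base_filters=8, patch_size=16)
        model = build_unet3d(cfg)
        channels = [blk.layers[0].c_out for blk in model.net.enc_blocks]
        assert channels == [8, 16, 32]

    def test_patch_edge_must_divide_by_pow2_depth(self):
        with pytest.raises(ParameterError):
            UNetConfig(depth=4, patch_size=24)

    def test_default_config_matches_reference_training_setup(self):
        cfg = UNetConfig()
        assert (cfg.batch_size, cfg.dropout_rate, cfg.learning_rate, cfg.epochs) == (
            16,
            0.2,
            0.001,
            20,
        )
        assert cfg.optimizer_name == "adam" and cfg.loss_name == "dice"


class TestDiceLoss:
    def test_perfect_prediction_near_zero(self):
        t = np.zeros((8, 8, 8))
        t[2:5, 2:5, 2:5] = 1
        assert dice_loss(t, t) < 0.05

    def test_fully_wrong_prediction_near_one(self):
        t = np.zeros((8, 8, 8))
        t[:4] = 1
        assert dice_loss(1 - t, t) > 0.95

    def test_half_overlap_example_exact_at_zero_smoothing(self):
        # |p ∩ t| = 1, |p| = |t| = 2 -> loss = 1 - 2*1/4 = 0.5
        p = np.zeros((4, 4, 4))
        t = np.zeros((4, 4, 4))
        p[0, 0, 0] = p[0, 0, 1] = 1
        t[0, 0, 1] = t[0, 0, 2] = 1
        assert dice_loss(p, t, smooth=0.0) == pytest.approx(0.5)

    def test_complements_dsc_for_hard_predictions(self, random_mask_pair):
        from infarctseg import dsc

        x, y = random_mask_pair()
        got = dice_loss(x.data.astype(float), y.data.astype(float), smooth=0.0)
        assert got == pytest.approx(1.0 - dsc(x, y), abs=1e-12)

    def test_nan_rejected(self):
        bad = np.zeros((4, 4, 4))
        bad[0, 0, 0] = np.nan
        with pytest.raises(InputError):
            dice_loss(bad, np.zeros((4, 4, 4)))

    def test_out_of_range_probabilities_rejected(self):
        with pytest.raises(InputError):
            dice_loss(np.full((4, 4, 4), 1.5), np.zeros((4, 4, 4)))


class TestBackpropagation:
    def test_gradients_match_finite_differences(self):
        """Analytic gradients of the full softmax+Dice objective vs central differences."""
        from infarctseg import nn as nn_mod
        from infarctseg.unet3d import _dice_loss_and_grad, _softmax_channels

        orig_dtype = nn_mod.DTYPE
        nn_mod.DTYPE = np.float64  # finite differences need more precision than float32
        try:
            cfg = UNetConfig(depth=2, base_filters=2, dropout_rate=0.0, patch_size=8, seed=3)
            net = build_unet3d(cfg).net
            for layer in net._all_layers():
                if hasattr(layer, "momentum"):
                    layer.momentum = 0.0  # freeze running stats so loss_fn is a pure function
            rng = np.random.default_rng(0)
            x = rng.random((2, 1, 8, 8, 8))
            t = (rng.random((2, 8, 8, 8)) > 0.7).astype(np.float64)

            def loss_fn():
                p = _softmax_channels(net.forward_logits(x, training=True))
                loss, dp1 = _dice_loss_and_grad(p[:, 1], t, 1.0)
                return loss, p, dp1

            net.zero_grad()
            _, p, dp1 = loss_fn()
            g1 = dp1 * p[:, 1] * p[:, 0]
            net.backward(np.stack([-g1, g1], axis=1))
            grads = [g.copy() for g in net.gradients()]

            eps, worst = 1e-6, 0.0
            for par, gr in zip(net.parameters(), grads):
                flat, gflat = par.reshape(-1), gr.reshape(-1)
                for i in rng.choice(flat.size, size=min(2, flat.size), replace=False):
                    orig = flat[i]
                    flat[i] = orig + eps
                    lp, _, _ = loss_fn()
                    flat[i] = orig - eps
                    lm, _, _ = loss_fn()
                    flat[i] = orig
                    num = (lp - lm) / (2 * eps)
                    ana = gflat[i]
                    worst = max(worst, abs(num - ana) / max(abs(num), abs(ana), 1e-10))
            assert worst < 1e-4
        finally:
            nn_mod.DTYPE = orig_dtype


def _toy_pair(seed=0, shape=(16, 16, 16)):
    rng = np.random.default_rng(seed)
    x = rng.random(shape).astype(np.float32) * 0.2
    t = np.zeros(shape, dtype=np.float32)
    t[4:10, 4:10, 4:10] = 1
    x[t.astype(bool)] += 0.8
    return x, t


class TestTraining:
    def test_zero_epochs_is_identity(self):
        cfg = UNetConfig(**{**TINY, "epochs": 0})
        model = build_unet3d(cfg)
        before = [p.copy() for p in model.net.parameters()]
        x, t = _toy_pair()
        out = train(model, [(x, t)], [], cfg)
        assert out.history == []
        for a, b in zip(before, out.net.parameters()):
            np.testing.assert_array_equal(a, b)

    def test_empty_training_set_rejected(self):
        cfg = UNetConfig(**TINY)
        with pytest.raises(InputError):
            train(build_unet3d(cfg), [], [], cfg)

    def test_seeded_training_is_reproducible(self):
        x, t = _toy_pair()
        cfg = UNetConfig(**{**TINY, "dropout_rate": 0.2, "seed": 42})
        h1 = train(build_unet3d(cfg), [(x, t)] * 3, [(x, t)], cfg).history
        h2 = train(build_unet3d(cfg), [(x, t)] * 3, [(x, t)], cfg).history
        assert h1 == h2

    def test_history_records_train_and_val_loss_per_epoch(self):
        x, t = _toy_pair()
        cfg = UNetConfig(**TINY)
        model = train(build_unet3d(cfg), [(x, t)], [(x, t)], cfg)
        assert len(model.history) == cfg.epochs
        assert all({"epoch", "train_loss", "val_loss"} <= set(h) for h in model.history)

    def test_loss_decreases_on_easy_memorization(self):
        x, t = _toy_pair()
        cfg = UNetConfig(**{**TINY, "epochs": 12, "learning_rate": 0.01, "batch_size": 1})
        model = train(build_unet3d(cfg), [(x, t)] * 2, [], cfg)
        losses = [h["train_loss"] for h in model.history]
        assert losses[-1] < losses[0] * 0.5

    def test_wrong_patch_size_rejected(self):
        cfg = UNetConfig(**TINY)
        x, t = _toy_pair(shape=(8, 8, 8))
        with pytest.raises(ShapeError):
            train(build_unet3d(cfg), [(x, t)], [], cfg)


class TestPrediction:
    def _patchset(self, data, subject="s"):
        return divide_patches(data, subject, patch_size=16, prune=True)

    def test_empty_patchset_gives_empty_predictions(self):
        model = build_unet3d(UNetConfig(**TINY))
        ps = self._patchset(np.zeros((16, 16, 16)))
        assert predict_patches(model, ps) == []

    def test_labels_binary_and_patch_shaped(self):
        model = build_unet3d(UNetConfig(**TINY))
        ps = self._patchset(np.random.default_rng(2).random((32, 16, 16)))
        preds = predict_patches(model, ps)
        assert len(preds) == 2
        for rid, lab in preds:
            assert lab.shape == (16, 16, 16)
            assert set(np.unique(lab)) <= {0, 1}

    def test_inference_is_deterministic(self):
        model = build_unet3d(UNetConfig(**{**TINY, "dropout_rate": 0.3}))
        ps = self._patchset(np.random.default_rng(3).random((16, 16, 16)))
        a = predict_patches(model, ps)
        b = predict_patches(model, ps)
        for (ra, la), (rb, lb) in zip(a, b):
            assert ra == rb
            np.testing.assert_array_equal(la, lb)


class TestSerialization:
    def test_checkpoint_round_trip_bit_compatible(self, tmp_path):
        x, t = _toy_pair()
        cfg = UNetConfig(**TINY)
        model = train(build_unet3d(cfg), [(x, t)], [(x, t)], cfg)
        save_model(model, tmp_path / "model")
        back = load_model(tmp_path / "model")
        assert back.history == model.history
        for a, b in zip(model.net.state(), back.net.state()):
            np.testing.assert_array_equal(a, b)
        ps = divide_patches(x, "s", patch_size=16)
        pa = predict_patches(model, ps)
        pb = predict_patches(back, ps)
        for (_, la), (_, lb) in zip(pa, pb):
            np.testing.assert_array_equal(la, lb)
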