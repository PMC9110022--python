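"""Fusion network: stacking, shapes, losses, training contracts, inference."""

import numpy as np
import pytest

from hsfuse.cube_io import (HyperspectralCube, PatchPair, RgbImage,
                            default_wavelengths)
from hsfuse.preprocess import box_downsample
from hsfuse.srrnet import (EarlyStopping, SrrConfig, SrrModel, build_srr,
                           evaluate_losses, load_checkpoint, reconstruct,
                           save_checkpoint, spatial_loss, spectral_loss,
                           stack_rgb, total_loss, train_srr)

TOY = dict(scale=4, patch_size=16, n_bands=4, duplication=(2, 1, 1),
           kappa=0.05, seed=3)


def toy_pairs(n, rng, scale=4, w=16, bands=4):
    wl = default_wavelengths(bands)
    pairs = []
    for _ in range(n):
        hr = HyperspectralCube(rng.uniform(0.2, 1.0, (w, w, bands)), wl)
        rgb = RgbImage(rng.random((w, w, 3)))
        pairs.append(PatchPair(hr, rgb, box_downsample(hr, scale), label=0))
    return pairs


class TestStackRgb:
    def test_production_counts_sum_to_87(self, rng):
        rgb = RgbImage(rng.random((4, 4, 3)))
        assert stack_rgb(rgb, (35, 35, 17)).shape == (4, 4, 87)

    def test_unit_counts_recover_rgb_up_to_order(self, rng):
        rgb = rng.random((4, 4, 3))
        out = stack_rgb(rgb, (1, 1, 1))      # order B, G, R
        np.testing.assert_array_equal(out[:, :, 0], rgb[:, :, 2])
        np.testing.assert_array_equal(out[:, :, 1], rgb[:, :, 1])
        np.testing.assert_array_equal(out[:, :, 2], rgb[:, :, 0])

    def test_duplication_multiplicities(self):
        rgb = np.zeros((1, 1, 3))
        rgb[0, 0] = [0.2, 0.5, 0.8]
        out = stack_rgb(rgb, (35, 35, 17))[0, 0]
        values, counts = np.unique(out, return_counts=True)
        assert dict(zip(values, counts)) == {0.2: 35, 0.5: 35, 0.8: 17}

    def test_bad_counts_rejected(self):
        with pytest.raises(ValueError):
            SrrConfig(n_bands=87, duplication=(35, 35, 18))


class TestConfig:
    def test_divisibility_constraints(self):
        with pytest.raises(ValueError, match="divisible"):
            SrrConfig(scale=3, patch_size=16)
        with pytest.raises(ValueError, match="divisible by 4"):
            SrrConfig(scale=2, patch_size=10, n_bands=87)

    def test_weights_must_be_convex(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SrrConfig(loss_weights=(0.7, 0.5))

    def test_lr_sizes_per_scale(self):
        # one 200-px patch: LR side 100/50/40/25/20 for the five scales
        for s, expected in [(2, 100), (4, 50), (5, 40), (8, 25), (10, 20)]:
            assert SrrConfig(scale=s).lr_size == expected


class TestArchitectureShapes:
    def test_full_scale_trace(self):
        """Layer trace at production configuration (4x, 200 px, 87 bands)."""
        model = build_srr(SrrConfig(scale=4))
        trace = dict(model.layer_shapes())
        assert trace["upsample"] == (87, 200, 200)
        assert trace["concat_rgb"] == (174, 200, 200)
        assert trace["enc1"] == (196, 200, 200)
        assert trace["enc2"] == (256, 200, 200)
        assert trace["enc3"] == (384, 100, 100)
        assert trace["enc4"] == (512, 100, 100)
        assert trace["enc5"] == (640, 50, 50)
        assert trace["enc6"] == (768, 50, 50)
        assert trace["concat_skip1"] == (1280, 100, 100)
        assert trace["dec1"] == (640, 100, 100)
        assert trace["dec2"] == (512, 100, 100)
        assert trace["concat_skip2"] == (512, 200, 200)
        assert trace["dec3"] == (256, 200, 200)
        assert trace["dec4"] == (194, 200, 200)
        assert trace["head"] == (87, 200, 200)
        assert trace["avgpool"] == (87, 50, 50)

    def test_scale5_lr_shape(self):
        model = build_srr(SrrConfig(scale=5))
        assert dict(model.layer_shapes())["avgpool"] == (87, 40, 40)

    def test_toy_forward_shape_contract(self, rng):
        cfg = SrrConfig(scale=2, patch_size=16, n_bands=6,
                        duplication=(2, 2, 2), kappa=0.05, seed=0)
        model = build_srr(cfg)
        lr = rng.random((1, 6, 8, 8)).astype(np.float32)
        rgb = rng.random((1, 6, 16, 16)).astype(np.float32)
        hr, lr_gen = model(lr, rgb)
        assert hr.shape == (1, 6, 16, 16)
        assert lr_gen.shape == (1, 6, 8, 8)


class TestLosses:
    def test_spatial_zero_when_panchromatics_agree(self, rng):
        stacked = rng.random((4, 4, 6))
        gen = np.repeat(stacked.mean(axis=2, keepdims=True), 6, axis=2)
        assert spatial_loss(stacked, gen) == pytest.approx(0.0, abs=1e-12)

    def test_spatial_unit_gap(self):
        assert spatial_loss(np.ones((3, 3, 2)), np.zeros((3, 3, 2))) == 1.0

    def test_spatial_matches_hand_sum(self, rng):
        a, b = rng.random((2, 2, 3)), rng.random((2, 2, 3))
        expected = sum((a[i, j].mean() - b[i, j].mean()) ** 2
                       for i in range(2) for j in range(2)) / 4
        assert spatial_loss(a, b) == pytest.approx(expected, abs=1e-12)

    def test_spectral_contracts(self, rng):
        cube = rng.random((2, 2, 3))
        assert spectral_loss(cube, cube) == 0.0
        assert spectral_loss(cube + 0.1, cube) == pytest.approx(0.01)
        other = rng.random((2, 2, 3))
        expected = sum((cube[i, j, k] - other[i, j, k]) ** 2
                       for i in range(2) for j in range(2)
                       for k in range(3)) / 12
        assert spectral_loss(cube, other) == pytest.approx(expected, abs=1e-12)

    def test_total_loss_convexity(self):
        assert total_loss(0.2, 0.4, (0.5, 0.5)) == pytest.approx(0.3)
        assert total_loss(0.7, 0.7, (0.3, 0.7)) == pytest.approx(0.7)
        assert total_loss(1.0, 0.0, (0.5, 0.5)) == pytest.approx(0.5)


class TestOperatorAgreement:
    def test_lr_head_equals_box_downsample(self, rng):
        """The average-pool head and the preprocessing box kernel are the
        same operator, for 20 random forward passes."""
        cfg = SrrConfig(**TOY)
        model = build_srr(cfg)
        for _ in range(20):
            lr = rng.random((1, 4, 4, 4)).astype(np.float32)
            rgb = rng.random((1, 4, 16, 16)).astype(np.float32)
            hr, lr_gen = model(lr, rgb)
            boxed = box_downsample(hr[0].transpose(1, 2, 0), 4)
            np.testing.assert_allclose(lr_gen[0].transpose(1, 2, 0), boxed,
                                       atol=1e-6)

    def test_spectral_loss_zero_for_perfect_reconstruction(self, rng):
        hr = rng.random((16, 16, 4))
        lr = box_downsample(hr, 4)
        assert spectral_loss(box_downsample(hr, 4), lr) == 0.0


class TestEarlyStopping:
    def test_plateau_stops_after_patience(self):
        stopper = EarlyStopping(patience=2)
        losses = [1.0, 0.8, 0.6, 0.5, 0.4, 0.35, 0.30, 0.30, 0.31]
        stopped_at = None
        for epoch, v in enumerate(losses):
            if stopper.update(v, epoch):
                stopped_at = epoch
                break
        assert stopped_at == 8
        assert stopper.best_epoch == 6

    def test_improvement_resets_counter(self):
        stopper = EarlyStopping(patience=2)
        for epoch, v in enumerate([1.0, 1.1, 0.9, 1.0, 0.8]):
            assert not stopper.update(v, epoch)


class TestTraining:
    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_srr([], SrrConfig(**TOY))

    def test_same_seed_identical_histories(self, rng):
        pairs = toy_pairs(4, rng)
        cfg = SrrConfig(**TOY, max_epochs=2, patience=5)
        _, h1 = train_srr(pairs, cfg)
        _, h2 = train_srr(pairs, cfg)
        assert h1["train_total"] == h2["train_total"]
        assert h1["val_total"] == h2["val_total"]

    def test_best_so_far_validation_decreases(self, rng):
        pairs = toy_pairs(6, rng)
        val = toy_pairs(2, rng)
        cfg = SrrConfig(**TOY, max_epochs=4, patience=10)
        _, hist = train_srr(pairs, cfg, val)
        best = np.minimum.accumulate(hist["val_total"])
        assert (np.diff(best) <= 0).all()
        assert best[-1] < hist["val_total"][0]

    def test_loss_evaluation_permutation_invariant(self, rng):
        pairs = toy_pairs(5, rng)
        cfg = SrrConfig(**TOY)
        model = build_srr(cfg)
        a = evaluate_losses(model, pairs)
        b = evaluate_losses(model, pairs[::-1])
        assert a["total"] == pytest.approx(b["total"], rel=1e-6)

    def test_gradients_finite_on_random_inputs(self, rng):
        cfg = SrrConfig(**TOY)
        model = build_srr(cfg)
        from hsfuse.srrnet import _batch_losses
        lr = rng.random((2, 4, 4, 4)).astype(np.float32)
        rgb = rng.random((2, 4, 16, 16)).astype(np.float32)
        *_, lt = _batch_losses(model, lr, rgb, track=True)
        lt.backward()
        for p in model.parameters():
            assert p.grad is not None and np.isfinite(p.grad).all()


class TestInference:
    def test_reconstruct_shape_and_clamp(self, rng):
        cfg = SrrConfig(**TOY)
        model = build_srr(cfg)
        wl = default_wavelengths(4)
        lr = HyperspectralCube(rng.random((4, 4, 4)), wl)
        rgb = RgbImage(rng.random((16, 16, 3)))
        out = reconstruct(lr, rgb, model)
        assert out.shape == (16, 16, 4)
        assert out.values.min() >= 0.0 and out.values.max() <= cfg.clamp_max
        again = reconstruct(lr, rgb, model)
        np.testing.assert_array_equal(out.values, again.values)

    def test_shape_mismatch_rejected(self, rng):
        model = build_srr(SrrConfig(**TOY))
        wl = default_wavelengths(4)
        bad_lr = HyperspectralCube(rng.random((5, 5, 4)), wl)
        with pytest.raises(ValueError, match="LR spatial"):
            reconstruct(bad_lr, RgbImage(rng.random((16, 16, 3))), model)

    def test_checkpoint_round_trip(self, tmp_path, rng):
        cfg = SrrConfig(**TOY)
        model = build_srr(cfg)
        path = save_checkpoint(model, tmp_path / "m.ckpt")
        back = load_checkpoint(path)
        assert back.config == cfg
        lr = rng.random((1, 4, 4, 4)).astype(np.float32)
        rgb = rng.random((1, 4, 16, 16)).astype(np.float32)
        np.testing.assert_array_equal(model(lr, rgb)[0], back(lr, rgb)[0])
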