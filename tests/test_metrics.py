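"""Metric correctness against independent brute-force oracles."""

import numpy as np
import pytest

from hsfuse.metrics import (ConfusionCounts, classification_metrics, mae_hsi,
                            psnr_hsi, roc_auc, sam, ssim_global)


# ---------------------------------------------------------------------------
# brute-force oracles (deliberately naive loops)
# ---------------------------------------------------------------------------

def psnr_oracle(ref, gen, peak):
    out = []
    for b in range(ref.shape[2]):
        mse = 0.0
        for i in range(ref.shape[0]):
            for j in range(ref.shape[1]):
                mse += (ref[i, j, b] - gen[i, j, b]) ** 2
        mse /= ref.shape[0] * ref.shape[1]
        out.append(10 * np.log10(peak ** 2 / mse))
    return float(np.mean(out)), np.array(out)


def mae_oracle(ref, gen):
    out = []
    for b in range(ref.shape[2]):
        s = 0.0
        for i in range(ref.shape[0]):
            for j in range(ref.shape[1]):
                s += abs(ref[i, j, b] - gen[i, j, b])
        out.append(s / (ref.shape[0] * ref.shape[1]))
    return float(np.mean(out)), np.array(out)


def sam_oracle_per_pixel(ref, gen):
    angles = []
    for i in range(ref.shape[0]):
        for j in range(ref.shape[1]):
            t, r = gen[i, j], ref[i, j]
            c = np.dot(t, r) / (np.linalg.norm(t) * np.linalg.norm(r))
            angles.append(np.degrees(np.arccos(min(1.0, max(-1.0, c)))))
    return float(np.mean(angles))


def sam_oracle_pooled(ref, gen):
    num = den_t = den_r = 0.0
    for i in range(ref.shape[0]):
        for j in range(ref.shape[1]):
            num += np.dot(gen[i, j], ref[i, j])
            den_t += np.dot(gen[i, j], gen[i, j])
            den_r += np.dot(ref[i, j], ref[i, j])
    return float(np.degrees(np.arccos(num / (np.sqrt(den_t) * np.sqrt(den_r)))))


def ssim_oracle(g, h, L):
    n = g.size
    mu_g = g.sum() / n
    mu_h = h.sum() / n
    var_g = ((g - mu_g) ** 2).sum() / n
    var_h = ((h - mu_h) ** 2).sum() / n
    cov = ((g - mu_g) * (h - mu_h)).sum() / n
    c1, c2 = (0.01 * L) ** 2, (0.03 * L) ** 2
    return ((2 * mu_g * mu_h + c1) * (2 * cov + c2)) / (
        (mu_g ** 2 + mu_h ** 2 + c1) * (var_g + var_h + c2))


# ---------------------------------------------------------------------------
# PSNR
# ---------------------------------------------------------------------------

class TestPsnr:
    def test_identical_cubes_are_infinite(self, rng):
        cube = rng.random((4, 4, 3))
        with pytest.warns(RuntimeWarning):
            mean, band = psnr_hsi(cube, cube.copy())
        assert np.isinf(band).all() and np.isinf(mean)

    def test_unit_mse_is_zero_db(self):
        ref = np.ones((4, 4, 1))
        gen = np.zeros((4, 4, 1))
        mean, band = psnr_hsi(ref, gen, peak=1.0)
        assert mean == pytest.approx(0.0) and band[0] == pytest.approx(0.0)

    def test_matches_oracle(self, rng):
        ref, gen = rng.random((4, 4, 3)), rng.random((4, 4, 3))
        mean, band = psnr_hsi(ref, gen, peak=1.0)
        omean, oband = psnr_oracle(ref, gen, 1.0)
        assert mean == pytest.approx(omean, abs=1e-9)
        np.testing.assert_allclose(band, oband, atol=1e-9)

    def test_noise_monotonicity(self, rng):
        ref = rng.random((16, 16, 4))
        values = []
        for sd in (0.01, 0.02, 0.05, 0.1, 0.2):
            gen = ref + rng.normal(0, sd, ref.shape)
            values.append(psnr_hsi(ref, gen)[0])
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError, match="shape"):
            psnr_hsi(rng.random((2, 2, 2)), rng.random((3, 3, 2)))


# ---------------------------------------------------------------------------
# MAE
# ---------------------------------------------------------------------------

class TestMae:
    def test_identical_is_zero(self, rng):
        cube = rng.random((3, 3, 2))
        assert mae_hsi(cube, cube)[0] == 0.0

    def test_constant_offset(self, rng):
        ref = rng.random((3, 3, 2))
        mean, band = mae_hsi(ref, ref + 0.05)
        assert mean == pytest.approx(0.05)
        assert mean * 100 == pytest.approx(5.0)   # percent reporting scale

    def test_matches_oracle(self, rng):
        ref, gen = rng.random((4, 4, 3)), rng.random((4, 4, 3))
        mean, band = mae_hsi(ref, gen)
        omean, oband = mae_oracle(ref, gen)
        assert mean == pytest.approx(omean, abs=1e-12)
        np.testing.assert_allclose(band, oband, atol=1e-12)


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

class TestSam:
    def test_identical_is_zero(self, rng):
        cube = rng.uniform(0.1, 1, (3, 3, 4))
        assert sam(cube, cube) == pytest.approx(0.0, abs=1e-5)

    def test_scale_invariance(self, rng):
        cube = rng.uniform(0.1, 1, (3, 3, 4))
        assert sam(cube, 2.7 * cube) == pytest.approx(0.0, abs=1e-5)
        assert sam(cube, 2.7 * cube, mode="pooled") == pytest.approx(0.0, abs=1e-4)

    def test_orthogonal_single_pixel(self):
        t = np.array([[[1.0, 0.0]]])
        r = np.array([[[0.0, 1.0]]])
        assert sam(r, t) == pytest.approx(90.0)

    def test_per_pixel_positive_scaling_invariance(self, rng):
        ref = rng.uniform(0.1, 1, (4, 4, 5))
        gen = rng.uniform(0.1, 1, (4, 4, 5))
        scales = rng.uniform(0.5, 3.0, (4, 4, 1))
        assert sam(ref, gen) == pytest.approx(sam(ref * scales, gen),
                                              abs=1e-6)

    def test_matches_oracles(self, rng):
        ref = rng.uniform(0.05, 1, (4, 4, 5))
        gen = rng.uniform(0.05, 1, (4, 4, 5))
        assert sam(ref, gen) == pytest.approx(sam_oracle_per_pixel(ref, gen),
                                              abs=1e-9)
        assert sam(ref, gen, mode="pooled") == pytest.approx(
            sam_oracle_pooled(ref, gen), abs=1e-9)

    def test_zero_spectrum_excluded(self):
        ref = np.ones((1, 2, 3))
        gen = np.ones((1, 2, 3))
        gen[0, 0] = 0.0
        assert sam(ref, gen) == pytest.approx(0.0, abs=1e-6)


# ---------------------------------------------------------------------------
# SSIM
# ---------------------------------------------------------------------------

class TestSsimGlobal:
    def test_identical_images(self, rng):
        g = rng.random((8, 8))
        assert ssim_global(g, g.copy()) == pytest.approx(1.0)

    def test_stated_constants_at_unit_range(self):
        L = 1.0
        assert (0.01 * L) ** 2 == pytest.approx(1e-4)
        assert (0.03 * L) ** 2 == pytest.approx(9e-4)

    def test_matches_statistics_oracle(self, rng):
        g, h = rng.random((8, 8)), rng.random((8, 8))
        assert ssim_global(g, h) == pytest.approx(ssim_oracle(g, h, 1.0),
                                                  abs=1e-12)

    def test_symmetry_and_bound(self, rng):
        g, h = rng.random((8, 8)), rng.random((8, 8))
        assert ssim_global(g, h) == pytest.approx(ssim_global(h, g), abs=1e-12)
        assert ssim_global(g, h) <= 1.0


# ---------------------------------------------------------------------------
# classification metrics
# ---------------------------------------------------------------------------

class TestClassificationMetrics:
    def test_perfect_counts(self):
        acc, sens, spec = classification_metrics(ConfusionCounts(1, 1, 0, 0))
        assert (acc, sens, spec) == (1.0, 1.0, 1.0)

    def test_sensitivity_ratio(self):
        _, sens, _ = classification_metrics(ConfusionCounts(85, 0, 0, 15))
        assert sens == pytest.approx(0.85)

    def test_undefined_sentinel(self):
        _, sens, _ = classification_metrics(ConfusionCounts(0, 5, 2, 0))
        assert np.isnan(sens)

    def test_accuracy_is_prevalence_weighted_mixture(self, rng):
        for _ in range(20):
            tp, tn, fp, fn = rng.integers(1, 50, 4)
            acc, sens, spec = classification_metrics(
                ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
            total = tp + tn + fp + fn
            prev = (tp + fn) / total
            assert acc == pytest.approx(prev * sens + (1 - prev) * spec)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)


class TestRocAuc:
    def test_perfect_separation(self):
        pairs = [(0.9, 1), (0.8, 1), (0.2, 0), (0.1, 0)]
        assert roc_auc(pairs) == 1.0

    def test_null_auc_near_half(self, rng):
        scores = rng.random(4000)
        labels = rng.integers(0, 2, 4000)
        assert roc_auc(list(zip(scores, labels))) == pytest.approx(0.5, abs=0.05)

    def test_toy_set_pair_counting(self):
        pairs = [(0.9, 1), (0.8, 0), (0.7, 1), (0.1, 0)]
        # concordant pairs among pos x neg: (0.9>0.8), (0.9>0.1), (0.7>0.1); 0.7<0.8
        assert roc_auc(pairs) == pytest.approx(3 / 4)

    def test_ties_get_half_credit(self):
        pairs = [(0.5, 1), (0.5, 0), (0.9, 1), (0.1, 0)]
        # brute force: (0.5 vs 0.5) = 0.5, (0.5 > 0.1) = 1, (0.9 > 0.5) = 1,
        # (0.9 > 0.1) = 1 -> 3.5/4
        assert roc_auc(pairs) == pytest.approx(3.5 / 4)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([(0.5, 1), (0.6, 1)])


def test_every_metric_matches_oracle_on_many_random_instances(rng):
    """50 random 8x8x5 instances, 1e-9 agreement with brute-force loops."""
    for _ in range(50):
        ref = rng.uniform(0.05, 1.0, (8, 8, 5))
        gen = rng.uniform(0.05, 1.0, (8, 8, 5))
        assert psnr_hsi(ref, gen)[0] == pytest.approx(
            psnr_oracle(ref, gen, 1.0)[0], abs=1e-9)
        assert mae_hsi(ref, gen)[0] == pytest.approx(
            mae_oracle(ref, gen)[0], abs=1e-9)
        assert sam(ref, gen) == pytest.approx(
            sam_oracle_per_pixel(ref, gen), abs=1e-9)
        g, h = ref.mean(axis=2), gen.mean(axis=2)
        assert ssim_global(g, h) == pytest.approx(ssim_oracle(g, h, 1.0),
                                                  abs=1e-9)
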