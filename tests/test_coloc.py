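"""Bleed-through subtraction, median filtering, Manders colocalization."""

import numpy as np
import pytest

from isletnet import (
    ChannelImage,
    ColocSimParams,
    auto_threshold,
    fit_channel_regression,
    generate_coloc_images,
    manders,
    manders_pipeline,
    median_filter,
    subtract_bleedthrough,
)
from isletnet.coloc import DegenerateFitError, UndefinedCoefficientError


class TestSubtractBleedthrough:
    def test_source_below_threshold_leaves_target(self):
        src = np.full((8, 8), 10.0)
        tgt = np.arange(64.0).reshape(8, 8)
        out = subtract_bleedthrough(src, tgt, mask_threshold=100.0)
        assert np.array_equal(out.pixels, tgt)

    def test_source_above_threshold_zeroes_everything(self):
        src = np.full((8, 8), 500.0)
        tgt = np.arange(64.0).reshape(8, 8)
        out = subtract_bleedthrough(src, tgt, mask_threshold=100.0)
        assert np.all(out.pixels == 0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            subtract_bleedthrough(np.zeros((4, 4)), np.zeros((5, 5)), 1.0)

    def test_removes_bleed_in_channel1_only_regions(self):
        # With the true channel-1 mask, residual channel-2 signal inside
        # channel-1-only spots drops to the background level.
        params = ColocSimParams(
            overlap_fraction=0.0, bleed_coefficient=0.3, noise_sd=20.0,
            rng_seed=7, n_spots=10,
        )
        ch1, ch2, truth = generate_coloc_images(params)
        # Use the ground-truth signal level as the detection threshold.
        corrected = subtract_bleedthrough(
            ch1, ch2, mask_threshold=0.02 * params.amplitude
        )
        only1 = truth.mask1 & ~truth.mask2
        background = ~truth.mask1 & ~truth.mask2
        bg_mean = ch2[background].mean()
        bg_sd = ch2[background].std()
        assert corrected.pixels[only1].mean() <= bg_mean + 2 * bg_sd


class TestMedianFilter:
    def test_constant_image_unchanged(self):
        img = np.full((10, 10), 7.0)
        assert np.array_equal(median_filter(img).pixels, img)

    def test_hot_pixel_removed(self):
        img = np.full((11, 11), 5.0)
        img[5, 5] = 60000.0
        assert np.all(median_filter(img, radius_px=2).pixels == 5.0)

    def test_matches_brute_force_disc_median(self):
        rng = np.random.default_rng(3)
        img = rng.integers(0, 1000, (20, 20)).astype(float)
        radius = 2
        out = median_filter(img, radius_px=radius).pixels
        h, w = img.shape
        for i in range(h):
            for j in range(w):
                vals = []
                for di in range(-radius, radius + 1):
                    for dj in range(-radius, radius + 1):
                        if di * di + dj * dj > radius * radius:
                            continue
                        ii = min(max(i + di, 0), h - 1)
                        jj = min(max(j + dj, 0), w - 1)
                        vals.append(img[ii, jj])
                assert out[i, j] == np.median(vals), (i, j)


class TestChannelRegression:
    def test_exact_affine_relation(self):
        rng = np.random.default_rng(0)
        p1 = rng.uniform(0, 100, (16, 16))
        a, b = fit_channel_regression(p1, 2.0 * p1 + 5.0)
        assert a == pytest.approx(2.0) and b == pytest.approx(5.0)

    def test_identity(self):
        rng = np.random.default_rng(1)
        p1 = rng.uniform(0, 100, (16, 16))
        a, b = fit_channel_regression(p1, p1)
        assert a == pytest.approx(1.0) and b == pytest.approx(0.0, abs=1e-9)

    def test_independent_noise_slope_near_zero(self):
        rng = np.random.default_rng(2)
        p1 = rng.uniform(0, 100, (100, 100))
        p2 = rng.uniform(0, 100, (100, 100))
        a, _ = fit_channel_regression(p1, p2)
        assert abs(a) < 0.02

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateFitError):
            fit_channel_regression(np.full((4, 4), 3.0), np.zeros((4, 4)))


class TestAutoThreshold:
    def test_two_population_fixture(self):
        # Correlated bright population, independent dim population: the
        # threshold should land between them.
        rng = np.random.default_rng(4)
        n = 2000
        dim1 = rng.integers(0, 100, n).astype(float)
        dim2 = rng.integers(0, 100, n).astype(float)
        bright1 = rng.integers(500, 1000, n).astype(float)
        bright2 = bright1 + rng.normal(0, 20, n)
        p1 = np.r_[dim1, bright1].reshape(40, -1)
        p2 = np.clip(np.r_[dim2, bright2], 0, None).reshape(40, -1)
        a, b = fit_channel_regression(p1, p2)
        t, warn = auto_threshold(p1, p2, a, b)
        assert not warn
        assert 100 <= t <= 500

    def test_independent_channels_threshold_near_max(self):
        rng = np.random.default_rng(5)
        p1 = rng.integers(0, 1000, (40, 40)).astype(float)
        p2 = rng.integers(0, 1000, (40, 40)).astype(float)
        a, b = fit_channel_regression(p1, p2)
        t, warn = auto_threshold(p1, p2, a, b)
        assert not warn
        # Correlation is already ~0 near the top of the intensity range.
        assert t > np.quantile(p1, 0.8)

    def test_perfectly_correlated_warns(self):
        rng = np.random.default_rng(6)
        p1 = rng.uniform(0, 1000, (20, 20))
        p2 = 3.0 * p1
        with pytest.warns(UserWarning):
            t, warn = auto_threshold(p1, p2, 3.0, 0.0)
        assert warn and t == p1.min()


class TestManders:
    def test_all_pixels_counted_when_threshold_below_min(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(10, 100, (8, 8))
        res = manders(p, p, threshold=5.0, a=1.0, b=0.0)
        assert res.m1 == 1.0 and res.m2 == 1.0

    def test_threshold_above_max_gives_zero(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(10, 100, (8, 8))
        res = manders(p, p, threshold=1e6, a=1.0, b=0.0)
        assert res.m1 == 0.0

    def test_four_pixel_worked_example(self):
        p1 = np.array([[10.0, 0.0], [10.0, 0.0]])
        p2 = np.array([[10.0, 10.0], [0.0, 0.0]])
        res = manders(p1, p2, threshold=5.0, a=1.0, b=0.0)
        assert res.m1 == 1.0 and res.m2 == 1.0
        res15 = manders(p1, p2, threshold=15.0, a=1.0, b=0.0)
        assert res15.m1 == 0.0

    def test_monotone_nonincreasing_in_threshold(self):
        rng = np.random.default_rng(9)
        p1 = rng.uniform(0, 1000, (16, 16))
        p2 = rng.uniform(0, 1000, (16, 16))
        m1s = [manders(p1, p2, t, 1.0, 0.0).m1 for t in np.linspace(0, 1100, 30)]
        m2s = [manders(p1, p2, t, 1.0, 0.0).m2 for t in np.linspace(0, 1100, 30)]
        assert np.all(np.diff(m1s) <= 0) and np.all(np.diff(m2s) <= 0)

    def test_rescaling_invariance(self):
        rng = np.random.default_rng(10)
        p1 = rng.uniform(0, 100, (12, 12))
        p2 = rng.uniform(0, 100, (12, 12))
        base = manders(p1, p2, 40.0, 1.2, 3.0)
        scaled = manders(5 * p1, 5 * p2, 200.0, 1.2, 15.0)
        assert scaled.m1 == pytest.approx(base.m1)
        assert scaled.m2 == pytest.approx(base.m2)

    def test_zero_channel_rejected(self):
        with pytest.raises(UndefinedCoefficientError):
            manders(np.zeros((4, 4)), np.ones((4, 4)), 0.0, 1.0, 0.0)


class TestPipelineOrder:
    def test_full_overlap_gives_unit_coefficients(self):
        params = ColocSimParams(
            overlap_fraction=1.0, bleed_coefficient=0.0, noise_sd=0.0, rng_seed=11
        )
        ch1, ch2, _ = generate_coloc_images(params)
        res = manders_pipeline(ChannelImage(ch1), ChannelImage(ch2))
        assert res.m1 == pytest.approx(1.0, abs=0.05)
        assert res.m2 == pytest.approx(1.0, abs=0.05)

    def test_disjoint_spots_score_below_full_overlap(self):
        # With no true colocalization the channels are anti-associated,
        # the fitted slope a is negative and the channel-2 threshold
        # aT + b is uninformative (M2 stays near 1 because the mapped
        # threshold drops below zero); the channel-1 coefficient still falls
        # well below the full-overlap value.
        disjoint = ColocSimParams(
            overlap_fraction=0.0, bleed_coefficient=0.0, noise_sd=10.0,
            n_spots=8, rng_seed=12,
        )
        full = ColocSimParams(
            overlap_fraction=1.0, bleed_coefficient=0.0, noise_sd=10.0,
            n_spots=8, rng_seed=12,
        )
        r_dis = manders_pipeline(*map(ChannelImage, generate_coloc_images(disjoint)[:2]))
        r_full = manders_pipeline(*map(ChannelImage, generate_coloc_images(full)[:2]))
        assert r_full.m1 > 0.9
        assert r_dis.m1 < 0.6
        assert r_dis.m1 < r_full.m1 - 0.3

    def test_subtraction_and_filter_order_matters(self):
        # Correct order: bleed-through subtraction, then median filter.
        # Reversing the order smears the bleed signal before masking and
        # changes the result, so a swap cannot go unnoticed.
        params = ColocSimParams(
            overlap_fraction=0.0, bleed_coefficient=0.5, noise_sd=30.0, rng_seed=13
        )
        ch1, ch2, _ = generate_coloc_images(params)
        thr = float(np.quantile(ch1, 0.9))
        correct = median_filter(subtract_bleedthrough(ch1, ch2, thr)).pixels
        swapped = subtract_bleedthrough(
            median_filter(ch1).pixels, median_filter(ch2).pixels, thr
        ).pixels
        assert not np.array_equal(correct, swapped)
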