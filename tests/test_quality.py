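"""Quality metrics against independent brute-force oracles."""

from __future__ import annotations

import math
import warnings

import numpy as np
import pytest

from octadc.quality import (
    SSIMParams,
    average_repeats,
    axial_profile,
    difference_image,
    evaluate_pairs,
    mse,
    ms_ssim,
    psnr,
    ssim,
)


# --------------------------------------------------------------------------
# independent oracles: explicit window loops, no shared code with the
# implementation


def gaussian_window(size=11, sigma=1.5):
    r = np.arange(size) - (size - 1) / 2
    g = np.exp(-(r**2) / (2 * sigma**2))
    w = np.outer(g, g)
    return w / w.sum()


def ssim_oracle(x, y, params: SSIMParams):
    """Sliding-window evaluation of the similarity index, one window at a
    time, with weighted means/variances computed longhand."""
    w = gaussian_window(params.window_size, params.window_sigma)
    n = params.window_size
    c1, c2 = params.c1, params.c2
    vals_l, vals_cs = [], []
    for i in range(x.shape[0] - n + 1):
        for j in range(x.shape[1] - n + 1):
            px = x[i : i + n, j : j + n]
            py = y[i : i + n, j : j + n]
            mx = (w * px).sum()
            my = (w * py).sum()
            vx = (w * px * px).sum() - mx * mx
            vy = (w * py * py).sum() - my * my
            cxy = (w * px * py).sum() - mx * my
            vals_l.append((2 * mx * my + c1) / (mx * mx + my * my + c1))
            vals_cs.append((2 * cxy + c2) / (vx + vy + c2))
    return (
        float(np.mean(np.array(vals_l) * np.array(vals_cs))),
        float(np.mean(vals_l)),
        float(np.mean(vals_cs)),
    )


def downsample_oracle(img):
    h, q = img.shape
    img = img[: h - h % 2, : q - q % 2]
    return (img[::2, ::2] + img[1::2, ::2] + img[::2, 1::2] + img[1::2, 1::2]) / 4


def ms_ssim_oracle(x, y, params: SSIMParams):
    m = params.n_scales
    weights = np.array(params.weights[:m])
    weights = weights / weights.sum()
    total = 1.0
    for j in range(m):
        full_mean, _, csmean = ssim_oracle(x, y, params)
        if j == m - 1:
            mean = full_mean
        else:
            mean = csmean
        if mean < 0 and weights[j] != 1.0:
            mean = 0.0
        total *= mean ** weights[j]
        if j < m - 1:
            x, y = downsample_oracle(x), downsample_oracle(y)
    return total


def psnr_oracle(f, g, s):
    err = 0.0
    m, n = f.shape
    for i in range(m):
        for j in range(n):
            err += (f[i, j] - g[i, j]) ** 2
    return 10 * math.log10(s**2 / (err / (m * n)))


# --------------------------------------------------------------------------


class TestMse:
    def test_identical_zero(self, rng):
        x = rng.random((5, 5))
        assert mse(x, x) == 0.0

    def test_constant_offset(self):
        assert mse(np.zeros((2, 2)), np.full((2, 2), 10.0)) == 100.0

    def test_matches_elementwise_sum(self, rng):
        f, g = rng.random((4, 4)), rng.random((4, 4))
        brute = sum((f[i, j] - g[i, j]) ** 2 for i in range(4) for j in range(4)) / 16
        assert mse(f, g) == pytest.approx(brute, rel=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            mse(np.zeros((2, 2)), np.zeros((2, 3)))


class TestPsnr:
    def test_zero_db_case(self):
        f, g = np.zeros((3, 3)), np.full((3, 3), 10.0)
        assert psnr(f, g, s=10.0) == pytest.approx(0.0)

    def test_unit_error_closed_form(self):
        f = np.zeros((4, 4))
        assert psnr(f, f + 1.0, s=255.0) == pytest.approx(20 * math.log10(255), rel=1e-9)

    def test_identical_images_infinite_with_warning(self, rng):
        x = rng.random((4, 4))
        with pytest.warns(RuntimeWarning):
            assert psnr(x, x) == math.inf

    def test_auto_peak_uses_reconstructed_image(self, rng):
        f = rng.random((8, 8))
        g = rng.random((8, 8)) * 0.5
        assert psnr(f, g) == pytest.approx(psnr(f, g, s=g.max()))
        # asymmetric by definition in auto mode
        assert psnr(f, g) != pytest.approx(psnr(g, f))


class TestSsim:
    def test_self_similarity_is_one(self, rng):
        x = rng.random((32, 32))
        assert ssim(x, x) == pytest.approx(1.0, abs=1e-9)

    def test_constant_images_closed_form(self):
        a, b = 0.4, 0.7
        x, y = np.full((16, 16), a), np.full((16, 16), b)
        p = SSIMParams()
        expected = (2 * a * b + p.c1) / (a * a + b * b + p.c1)
        assert ssim(x, y, p) == pytest.approx(expected, rel=1e-9)

    def test_matches_windowed_oracle(self, rng):
        p = SSIMParams()
        for _ in range(3):
            x = rng.random((24, 24))
            y = np.clip(x + rng.normal(0, 0.1, x.shape), 0, 1)
            expected, _, _ = ssim_oracle(x, y, p)
            assert ssim(x, y, p) == pytest.approx(expected, abs=1e-9)

    def test_symmetry(self, rng):
        x, y = rng.random((24, 24)), rng.random((24, 24))
        assert ssim(x, y) == pytest.approx(ssim(y, x), abs=1e-9)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            ssim(np.zeros((8, 8)), np.zeros((8, 8)))


class TestMsSsim:
    def test_self_similarity_is_one(self, rng):
        x = rng.random((64, 64))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert ms_ssim(x, x) == pytest.approx(1.0, abs=1e-9)

    def test_single_scale_equals_ssim(self):
        # local generator: the equality must hold for uncorrelated pairs too,
        # where the mean similarity is legitimately negative
        local = np.random.default_rng(987)
        for _ in range(5):
            x, y = local.random((32, 32)), local.random((32, 32))
            p = SSIMParams(n_scales=1, weights=(1.0,))
            assert ms_ssim(x, y, p) == pytest.approx(ssim(x, y), abs=1e-12)

    def test_matches_per_scale_oracle(self, rng):
        p = SSIMParams(n_scales=3)
        x = rng.random((64, 64))
        y = np.clip(x + rng.normal(0, 0.05, x.shape), 0, 1)
        assert ms_ssim(x, y, p) == pytest.approx(ms_ssim_oracle(x, y, p), abs=1e-6)

    def test_scale_auto_reduction_warns(self, rng):
        x = rng.random((16, 16))
        with pytest.warns(RuntimeWarning, match="scales"):
            ms_ssim(x, x)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            ms_ssim(np.zeros((8, 8)), np.zeros((8, 8)))

    def test_monotone_degradation_under_noise(self, rng):
        x = rng.random((64, 64))
        p = SSIMParams(n_scales=3)
        vals = []
        noise = rng.normal(0, 1, x.shape)
        for sigma in (0.0, 0.02, 0.05, 0.1, 0.2):
            vals.append(ms_ssim(x, np.clip(x + sigma * noise, 0, 1), p))
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_symmetry(self, rng):
        p = SSIMParams(n_scales=3)
        x, y = rng.random((48, 48)), rng.random((48, 48))
        assert ms_ssim(x, y, p) == pytest.approx(ms_ssim(y, x, p), abs=1e-9)


class TestAverageRepeats:
    def test_groupwise_mean(self, rng):
        imgs = [rng.random((4, 4)) for _ in range(8)]
        out = average_repeats(imgs, 4)
        assert len(out) == 2
        np.testing.assert_allclose(out[0], np.mean(imgs[:4], axis=0))
        np.testing.assert_allclose(out[1], np.mean(imgs[4:], axis=0))

    def test_identity_cases(self, rng):
        img = rng.random((4, 4))
        np.testing.assert_array_equal(average_repeats([img] * 4, 4)[0], img)
        np.testing.assert_array_equal(average_repeats([img], 1)[0], img)

    def test_indivisible_rejected(self, rng):
        with pytest.raises(ValueError):
            average_repeats([np.zeros((2, 2))] * 5, 2)


class TestDifferenceImage:
    def test_identical_gives_zero_map(self, rng):
        x = rng.random((8, 8))
        np.testing.assert_array_equal(difference_image(x, x), 0.0)

    def test_constant_offset(self, rng):
        x = rng.random((8, 8))
        np.testing.assert_allclose(difference_image(x, x + 0.1), 0.1)

    def test_mean_equals_mae(self, rng):
        f, g = rng.random((8, 8)), rng.random((8, 8))
        assert difference_image(f, g).mean() == pytest.approx(np.mean(np.abs(f - g)))

    def test_rendering_normalized_rgba(self, rng):
        from octadc.quality import render_difference

        diff = difference_image(rng.random((8, 8)), rng.random((8, 8)))
        rgba = render_difference(diff)
        assert rgba.shape == (8, 8, 4)
        assert np.all((rgba >= 0) & (rgba <= 1))


class TestAxialProfile:
    @staticmethod
    def _gaussian_volume(center=40.0, sigma=2.0, n=6, z=96, a=16):
        rows = np.arange(z)
        prof = np.exp(-((rows - center) ** 2) / (2 * sigma**2))
        return [np.tile(prof[:, None], (1, a)) for _ in range(n)]

    def test_gaussian_fwhm_closed_form(self):
        vol = self._gaussian_volume(sigma=2.0)
        ap = axial_profile(vol, column=8, n_bscans_avg=6, n_alines_avg=5)
        assert len(ap.peak_rows) == 1
        assert ap.peak_fwhm_rows[0] == pytest.approx(2 * math.sqrt(2 * math.log(2)) * 2.0, abs=0.05)

    def test_two_separated_peaks_located(self):
        rows = np.arange(96)
        prof = np.exp(-((rows - 30.0) ** 2) / 8) + 0.8 * np.exp(-((rows - 70.0) ** 2) / 8)
        vol = [np.tile(prof[:, None], (1, 16))] * 6
        ap = axial_profile(vol, column=8)
        np.testing.assert_allclose(ap.peak_rows, [30.0, 70.0], atol=1.0)

    def test_profile_is_mean_of_contributing_alines(self, rng):
        vol = [rng.random((32, 16)) for _ in range(6)]
        ap = axial_profile(vol, column=8, n_bscans_avg=6, n_alines_avg=5)
        expected = np.mean(np.stack(vol), axis=0)[:, 6:11].mean(axis=1)
        np.testing.assert_allclose(ap.intensity, expected)

    def test_window_out_of_bounds_rejected(self, rng):
        vol = [rng.random((32, 8))] * 6
        with pytest.raises(ValueError):
            axial_profile(vol, column=1, n_alines_avg=5)
        with pytest.raises(ValueError):
            axial_profile(vol, column=4, n_bscans_avg=10)


class TestEvaluatePairs:
    def test_perfect_prediction_bounds(self, rng):
        gts = [rng.random((64, 64)) for _ in range(2)]
        rows = evaluate_pairs(gts, gts, SSIMParams(n_scales=3))
        assert np.all(np.isinf(rows["psnr_db"]))
        np.testing.assert_allclose(rows["ms_ssim"], 1.0, atol=1e-9)
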