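import numpy as np
import pytest

from smlmdecorr import (
    DecorrConfig,
    RenderedImage,
    apodize,
    decorr_curve,
    estimate_resolution,
    find_peak,
    high_pass,
)
from smlmdecorr.decorr import Peak, _radial_freq
from _oracles import decorr_oracle

RADII_10 = np.linspace(0.1, 1.0, 10)


class TestApodize:
    def test_constant_image_is_unchanged(self):
        img = np.full((40, 40), 3.7)
        np.testing.assert_allclose(apodize(img, 10), img)

    def test_interior_pixels_untouched_and_edges_reach_mean(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 5, (50, 50))
        out = apodize(img, 10)
        np.testing.assert_allclose(out[10:40, 10:40], img[10:40, 10:40])
        np.testing.assert_allclose(out[0, :], img.mean())
        np.testing.assert_allclose(out[:, -1], img.mean())

    def test_zero_border_is_identity(self):
        img = np.arange(25.0).reshape(5, 5)
        np.testing.assert_array_equal(apodize(img, 0), img)

    def test_oversized_border_rejected(self):
        with pytest.raises(ValueError):
            apodize(np.zeros((10, 10)), 6)


class TestHighPass:
    def test_constant_image_maps_to_zero(self):
        out = high_pass(np.full((21, 21), 4.0), 0.3)
        assert np.max(np.abs(out)) <= 1e-12

    def test_huge_sigma_suppresses_everything(self):
        # residual scales like H(|k|max) = 1 - exp(-1/sigma^2), -> 0
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 1, (32, 32))
        assert np.max(np.abs(high_pass(img, 100.0))) <= 1e-3 * np.ptp(img)
        assert np.max(np.abs(high_pass(img, 1e4))) <= 1e-6 * np.ptp(img)

    def test_nyquist_grating_gain_matches_closed_form(self):
        n = 32
        grating = np.tile((-1.0) ** np.arange(n), (n, 1))  # |k| = 1 along x
        sigma = 0.2
        out = high_pass(grating, sigma)
        gain = 1.0 - np.exp(-1.0 / (2.0 * sigma**2))
        np.testing.assert_allclose(out, gain * grating, atol=1e-12)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            high_pass(np.zeros((8, 8)), 0.0)


class TestDecorrCurve:
    @pytest.mark.parametrize("shape", [(15, 15), (21, 21), (31, 31)])
    @pytest.mark.parametrize("sigma", [None, 0.2])
    def test_matches_direct_summation_oracle(self, shape, sigma):
        rng = np.random.default_rng(hash(shape) % 1000)
        img = rng.normal(size=shape)
        d = decorr_curve(img, RADII_10, sigma)
        ref = decorr_oracle(img, RADII_10, sigma)
        assert np.max(np.abs(d - ref)) <= 1e-10

    def test_flat_spectrum_closed_form(self):
        # one off-center bright pixel: |F| constant, so d(r) = sqrt(N_r/N_1)
        img = np.zeros((15, 15))
        img[3, 7] = 1.0
        d = decorr_curve(img, RADII_10)
        kr = _radial_freq(15, 15)
        n1 = np.count_nonzero((kr <= 1) & (kr > 0))
        expected = np.sqrt(
            [np.count_nonzero((kr <= r) & (kr > 0)) / n1 for r in RADII_10]
        )
        np.testing.assert_allclose(d, expected, atol=1e-12)

    def test_empty_mask_yields_zero(self):
        rng = np.random.default_rng(2)
        img = rng.normal(size=(15, 15))
        d = decorr_curve(img, np.array([0.01, 0.5]))
        assert d[0] == 0.0 and d[1] > 0.0

    def test_all_zero_image_gives_zero_curve(self):
        d = decorr_curve(np.zeros((15, 15)), RADII_10)
        assert not d.any()

    def test_values_bounded_in_unit_interval(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            img = rng.normal(size=(21, 21))
            d = decorr_curve(img, np.linspace(0.05, 1.0, 20))
            assert np.all(d >= 0.0) and np.all(d <= 1.0 + 1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        img = rng.normal(size=(21, 21))
        d1 = decorr_curve(img, RADII_10)
        d2 = decorr_curve(1234.5 * img, RADII_10)
        np.testing.assert_allclose(d1, d2, atol=1e-12)

    def test_non_increasing_radii_rejected(self):
        with pytest.raises(ValueError):
            decorr_curve(np.zeros((15, 15)), np.array([0.5, 0.5, 0.6]))


class TestFindPeak:
    def test_interior_maximum_with_drop(self):
        radii = np.linspace(0.1, 1.0, 10)
        d = np.array([0.1, 0.3, 0.5, 0.4, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1])
        pk = find_peak(d, radii)
        assert pk == Peak(pytest.approx(0.3), 0.5, boundary=False)

    def test_plateaued_boundary_is_sampling_limited_peak(self):
        radii = np.linspace(0.1, 1.0, 10)
        d = np.array([0.1, 0.3, 0.5, 0.6, 0.7, 0.75, 0.78, 0.8, 0.8, 0.8])
        pk = find_peak(d, radii)
        assert pk is not None and pk.boundary and pk.r == 1.0

    def test_curve_still_rising_at_nyquist_yields_none(self):
        radii = np.linspace(0.1, 1.0, 10)
        d = np.linspace(0.1, 0.8, 10)  # strictly rising, no plateau
        assert find_peak(d, radii) is None

    def test_low_amplitude_peak_rejected(self):
        radii = np.linspace(0.1, 1.0, 10)
        d = np.array([0.0, 5e-4, 1e-4, 0, 0, 0, 0, 0, 0, 0.0])
        assert find_peak(d, radii, min_amplitude=1e-3) is None

    def test_argmax_ties_break_toward_largest_radius(self):
        radii = np.linspace(0.1, 1.0, 10)
        d = np.array([0.1, 0.5, 0.3, 0.5, 0.1, 0.0, 0.0, 0.0, 0.0, 0.0])
        pk = find_peak(d, radii)
        assert pk.r == pytest.approx(0.4)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            find_peak(np.zeros(5), np.zeros(4))


class TestEstimateResolution:
    def test_constant_image_has_no_estimate(self):
        img = RenderedImage(values=np.ones((101, 101)), pixel_size=1.0)
        assert estimate_resolution(img).status == "no_estimate"

    def test_band_limited_noise_recovers_cutoff(self):
        # white noise ideally low-passed at normalized cutoff 0.5: the
        # spectral support ends mid-band, so the cutoff must be found there
        rng = np.random.default_rng(1)
        img = rng.normal(size=(255, 255))
        F = np.fft.fft2(img)
        F[_radial_freq(255, 255) > 0.5] = 0.0
        img = np.real(np.fft.ifft2(F))
        res = estimate_resolution(RenderedImage(values=img, pixel_size=1.0))
        assert res.status == "estimate"
        assert 0.45 <= res.r_max <= 0.55
        assert res.resolution_nm == pytest.approx(4.0, rel=0.11)

    def test_grating_line_spectrum_located_to_grid_precision(self):
        # 32 cycles over 255 px (commensurate with the DFT grid, period
        # ~7.97 px) puts a line at normalized frequency ~0.251
        n = 255
        img = np.tile(np.cos(2 * np.pi * 32 * np.arange(n) / n), (n, 1)) + 1.0
        res = estimate_resolution(
            RenderedImage(values=img, pixel_size=1.0),
            DecorrConfig(apod_border=0),
        )
        assert res.status == "estimate"
        assert abs(res.r_max - 0.25) <= 1.0 / 50 + 1e-9
        assert res.resolution_nm == pytest.approx(8.0, rel=0.1)

    def test_resolution_r_max_identity_and_scale_invariance(self, dense_table, fov):
        from smlmdecorr import bilinear_render

        img = bilinear_render(dense_table, 10.0, fov)
        res = estimate_resolution(img)
        assert res.status == "estimate"
        assert res.resolution_nm * res.r_max == pytest.approx(2.0 * 10.0, rel=1e-12)
        scaled = RenderedImage(values=img.values * 37.5, pixel_size=10.0)
        res2 = estimate_resolution(scaled)
        assert res2.resolution_nm == pytest.approx(res.resolution_nm, rel=1e-9)

    def test_too_small_image_rejected_with_advice(self):
        img = RenderedImage(values=np.ones((30, 30)), pixel_size=1.0)
        with pytest.raises(ValueError, match="apod_border"):
            estimate_resolution(img)

    def test_even_sides_are_cropped_not_an_error(self):
        rng = np.random.default_rng(9)
        img = RenderedImage(values=rng.normal(size=(64, 100)), pixel_size=1.0)
        res = estimate_resolution(img, DecorrConfig(apod_border=5))
        assert len(res.curves[0].d) == 50
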