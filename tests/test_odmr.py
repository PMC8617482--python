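"""ODMR pipeline: binning, per-pixel dip fits, field maps, background
removal and the line-cut ΔB_NV metric."""

import warnings

import numpy as np
import pytest

from qdmpipe import ParticleModel, SensorConfig
from qdmpipe.magnetostatics import AppliedField
from qdmpipe.odmr import (
    analyze_stack,
    auto_signal_mask,
    bin2x2,
    field_map_from_fits,
    fit_odmr_pixel,
    fit_stack,
    linecut_delta_b,
    subtract_background,
)
from qdmpipe.sensor import FieldMap, effective_field_image
from qdmpipe.spectra import fit_lorentzian_grid, lorentzian_dip
from qdmpipe.synth import synth_odmr_stack

from conftest import SMALL_EXTENT, SMALL_OVERSAMPLE


class TestBin2x2:
    def test_constant_frame_unchanged(self):
        frames = np.full((3, 8, 8), 2.7)
        assert np.allclose(bin2x2(frames), 2.7)

    def test_block_mean(self):
        frame = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert bin2x2(frame) == pytest.approx(2.5)

    def test_twice_equals_4x4_mean(self):
        rng = np.random.default_rng(1)
        frame = rng.normal(size=(16, 16))
        twice = bin2x2(bin2x2(frame))
        direct = frame.reshape(4, 4, 4, 4).mean(axis=(1, 3))
        assert np.allclose(twice, direct, rtol=1e-12)

    def test_odd_trailing_dimension_dropped(self):
        frame = np.ones((5, 7))
        assert bin2x2(frame).shape == (2, 3)


class TestPixelFit:
    def test_noiseless_parameters_recovered(self):
        freqs = np.linspace(2750, 2850, 60)
        truth = (2800.0, 0.02, 8.0)
        fit = fit_odmr_pixel(freqs, lorentzian_dip(freqs, *truth))
        assert fit.valid
        assert fit.omega0 == pytest.approx(truth[0], rel=1e-6)
        assert fit.contrast == pytest.approx(truth[1], rel=1e-6)
        assert fit.gamma_width == pytest.approx(truth[2], rel=1e-6)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_odmr_pixel(np.arange(4.0), np.ones(4))

    def test_edge_pinned_resonance_flagged_invalid(self):
        freqs = np.linspace(2800, 2900, 40)
        # dip centered far outside the band
        fit = fit_odmr_pixel(freqs, lorentzian_dip(freqs, 2790.0, 0.02, 8.0))
        assert not fit.valid

    def test_vectorized_grid_matches_scipy_on_noiseless_spectra(self):
        freqs = np.linspace(2750, 2850, 80)
        rng = np.random.default_rng(3)
        w0s = rng.uniform(2780, 2820, size=12)
        spec = np.stack([lorentzian_dip(freqs, w, 0.02, 8.0) for w in w0s])
        spec = spec.T.reshape(len(freqs), 3, 4)
        w_fit, c_fit, g_fit, valid = fit_lorentzian_grid(freqs, spec)
        assert valid.all()
        assert np.allclose(w_fit.ravel(), w0s, atol=1e-5)
        assert np.allclose(c_fit, 0.02, rtol=1e-4)
        assert np.allclose(g_fit, 8.0, rtol=1e-4)


class TestFieldMapFromFits:
    def grids(self, *vals):
        return {"omega0": np.array([[v] for v in vals], dtype=float),
                "valid": np.ones((len(vals), 1), dtype=bool)}

    def test_separation_conversion(self, sensor):
        fits = {"minus": self.grids(2590.0), "plus": self.grids(3150.0)}
        fmap = field_map_from_fits(fits, sensor, 216e-9)
        assert fmap.values[0, 0] == pytest.approx(100.0)

    def test_equal_frequencies_give_zero(self, sensor):
        fits = {"minus": self.grids(2870.0), "plus": self.grids(2870.0)}
        fmap = field_map_from_fits(fits, sensor, 216e-9)
        assert fmap.values[0, 0] == pytest.approx(0.0)

    def test_single_dip_beyond_level_crossing(self, sensor):
        # at 1400 G the lower branch reads f = gamma*B - D
        fits = {"minus": self.grids(1050.0)}
        fmap = field_map_from_fits(fits, sensor, 216e-9, b0_gauss=1400.0)
        assert fmap.values[0, 0] == pytest.approx(1400.0)

    def test_invalid_pixels_propagate_as_nan(self, sensor):
        fits = {"minus": self.grids(2590.0, 2600.0),
                "plus": self.grids(3150.0, 3140.0)}
        fits["plus"]["valid"][1, 0] = False
        fmap = field_map_from_fits(fits, sensor, 216e-9)
        assert np.isnan(fmap.values[1, 0])

    def test_roundtrip_against_generator_field(self, sensor, particle):
        stack = synth_odmr_stack(particle, sensor, b0_gauss=100.0,
                                 photons_per_pixel=np.inf,
                                 extent=SMALL_EXTENT,
                                 oversample=SMALL_OVERSAMPLE)
        fmap = analyze_stack(stack, sensor)
        truth = effective_field_image(
            particle, AppliedField.from_gauss(100.0, sensor.nv_axis), sensor,
            extent=SMALL_EXTENT, oversample=SMALL_OVERSAMPLE, mask=False)
        assert np.nanmax(np.abs(fmap.values - truth.values)) < 1e-3


class TestBackgroundSubtraction:
    def test_constant_map_gives_zero_signal(self):
        fmap = FieldMap(np.full((64, 64), 3.3), 216e-9)
        signal, background = subtract_background(fmap, sigma_coarse=8,
                                                 sigma_fine=4)
        assert np.allclose(signal.values, 0.0, atol=1e-12)
        assert np.allclose(background.values, 3.3, atol=1e-12)

    def test_planar_gradient_mostly_removed(self):
        n = 96
        yy, xx = np.mgrid[0:n, 0:n]
        grad = 0.01 * xx + 0.005 * yy  # span ~1.4 G
        fmap = FieldMap(grad, 216e-9)
        signal, _ = subtract_background(fmap, sigma_coarse=12, sigma_fine=6)
        core = signal.values[12:-12, 12:-12]
        assert np.max(np.abs(core)) < 0.01 * np.ptp(grad)

    def test_injected_pattern_recovered_under_gradient(self, sensor, particle):
        truth = effective_field_image(
            particle, AppliedField.from_gauss(100.0, sensor.nv_axis), sensor,
            extent=SMALL_EXTENT, oversample=SMALL_OVERSAMPLE, mask=False)
        n = truth.shape[0]
        yy, xx = np.mgrid[0:n, 0:n]
        gradient = 0.002 * xx + 0.001 * yy
        fmap = FieldMap(truth.values + gradient, truth.pixel)
        mask = auto_signal_mask(fmap, psf_fwhm=sensor.psf_fwhm, sigma_fine=3)
        signal, _ = subtract_background(fmap, mask, sigma_coarse=6,
                                        sigma_fine=3)
        p2p_true = np.ptp(truth.values)
        p2p_rec = np.ptp(signal.values[mask])
        assert p2p_rec == pytest.approx(p2p_true, rel=0.05)

    def test_oversized_mask_warns(self):
        fmap = FieldMap(np.zeros((32, 32)), 216e-9)
        mask = np.ones((32, 32), dtype=bool)
        with pytest.warns(UserWarning):
            subtract_background(fmap, mask, sigma_coarse=4, sigma_fine=2)


class TestAutoSignalMask:
    def test_mask_covers_both_lobes(self, sensor, particle):
        fmap = effective_field_image(
            particle, AppliedField.from_gauss(100.0, sensor.nv_axis), sensor,
            extent=SMALL_EXTENT, oversample=SMALL_OVERSAMPLE, mask=False)
        mask = auto_signal_mask(fmap, psf_fwhm=sensor.psf_fwhm, sigma_fine=3)
        i_max = np.unravel_index(np.argmax(fmap.values), fmap.shape)
        i_min = np.unravel_index(np.argmin(fmap.values), fmap.shape)
        assert mask[i_max] and mask[i_min]

    def test_fixed_disk_area_on_pure_noise(self):
        rng = np.random.default_rng(8)
        a = auto_signal_mask(FieldMap(rng.normal(size=(40, 40)), 216e-9))
        b = auto_signal_mask(FieldMap(rng.normal(size=(40, 40)), 216e-9))
        assert abs(int(a.sum()) - int(b.sum())) <= 8  # edge clipping only

    def test_mask_translates_with_signal(self, sensor, particle):
        pix = sensor.binned_pixel
        shifted = ParticleModel(center=(3 * pix, 0, 250e-9), diameter=365e-9,
                                chi_v=0.053)
        m0 = auto_signal_mask(effective_field_image(
            particle, AppliedField.from_gauss(100.0, sensor.nv_axis), sensor,
            extent=SMALL_EXTENT, oversample=SMALL_OVERSAMPLE, mask=False),
            sigma_fine=3)
        m1 = auto_signal_mask(effective_field_image(
            shifted, AppliedField.from_gauss(100.0, sensor.nv_axis), sensor,
            extent=SMALL_EXTENT, oversample=SMALL_OVERSAMPLE, mask=False),
            sigma_fine=3)
        assert np.array_equal(np.roll(m0, 3, axis=1)[:, 3:-3], m1[:, 3:-3])


def double_gaussian_profile(n, pix, a_pos, a_neg, sep, width, offset=0.0):
    x = (np.arange(n) + 0.5) * pix
    c = x.mean()
    return (offset
            + a_pos * np.exp(-0.5 * ((x - c + sep / 2) / width) ** 2)
            - a_neg * np.exp(-0.5 * ((x - c - sep / 2) / width) ** 2))


class TestLineCut:
    def test_exact_double_gaussian_recovered(self):
        pix = 216e-9
        n = 80
        prof = double_gaussian_profile(n, pix, 0.2, 0.2, sep=30 * pix,
                                       width=2 * pix)
        res = linecut_delta_b(FieldMap(np.tile(prof, (7, 1)), pix))
        assert res.delta_b == pytest.approx(0.4, rel=1e-6)

    def test_all_zero_map_gives_zero(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = linecut_delta_b(FieldMap(np.zeros((20, 20)), 216e-9))
        assert res.delta_b == pytest.approx(0.0, abs=1e-9)

    def test_invariant_under_constant_offset(self, sensor, particle):
        fmap = effective_field_image(
            particle, AppliedField.from_gauss(100.0, sensor.nv_axis), sensor,
            extent=SMALL_EXTENT, oversample=SMALL_OVERSAMPLE, mask=False)
        r0 = linecut_delta_b(fmap)
        r1 = linecut_delta_b(FieldMap(fmap.values + 7.0, fmap.pixel))
        assert r1.delta_b == pytest.approx(r0.delta_b, rel=1e-6)

    def test_delta_b_decreases_with_psf_width(self, particle):
        amps = []
        for fwhm in (300e-9, 450e-9, 700e-9):
            s = SensorConfig(psf_fwhm=fwhm)
            fmap = effective_field_image(
                particle, AppliedField.from_gauss(100.0, s.nv_axis), s,
                extent=SMALL_EXTENT, oversample=SMALL_OVERSAMPLE, mask=False)
            amps.append(linecut_delta_b(fmap).delta_b)
        assert amps[0] > amps[1] > amps[2]

    def test_error_is_background_sd(self):
        rng = np.random.default_rng(12)
        vals = 0.05 * rng.standard_normal((40, 40))
        mask = np.zeros((40, 40), dtype=bool)
        mask[15:25, 15:25] = True
        vals[18, 20], vals[22, 20] = 1.0, -1.0
        res = linecut_delta_b(FieldMap(vals, 216e-9), mask=mask)
        assert res.delta_b_err == pytest.approx(np.std(vals[~mask]), rel=1e-12)

    def test_noisy_delta_b_bias_below_reported_error(self, sensor, particle):
        """Shot noise at the default budget should not bias ΔB_NV by more
        than the reported background-SD error bar (30 repetitions, at the
        1400 G magnetizing field of the imaging experiments)."""
        from qdmpipe.sensor import centered_sweep_window

        s = sensor.with_window(centered_sweep_window(1400.0))
        truth_map = effective_field_image(
            particle, AppliedField.from_gauss(1400.0, s.nv_axis), s,
            extent=SMALL_EXTENT, oversample=SMALL_OVERSAMPLE, mask=False)
        mask = auto_signal_mask(truth_map, psf_fwhm=s.psf_fwhm, sigma_fine=3)
        truth = linecut_delta_b(truth_map, mask=mask).delta_b
        vals, errs = [], []
        for rep in range(30):
            stack = synth_odmr_stack(
                particle, s, b0_gauss=1400.0, photons_per_pixel=1e5,
                seed=1000 + rep, extent=SMALL_EXTENT,
                oversample=SMALL_OVERSAMPLE)
            fmap = analyze_stack(stack, s)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = linecut_delta_b(fmap, mask=mask)
            vals.append(res.delta_b)
            errs.append(res.delta_b_err)
        bias = abs(np.mean(vals) - truth)
        assert bias < np.mean(errs)
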