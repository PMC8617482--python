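"""Synthetic raw-data generator: ODMR sweeps, field series, T1 decays."""

import numpy as np
import pytest

from qdmpipe import ParticleModel
from qdmpipe.sensor import resonance_frequencies
from qdmpipe.spectra import lorentzian_dip, stretched_exp
from qdmpipe.synth import (
    DEFAULT_CONTRAST,
    log_spaced_taus,
    synth_field_series,
    synth_odmr_stack,
    synth_t1_stack,
)

from conftest import SMALL_EXTENT, SMALL_OVERSAMPLE

EXTENT = (2.16e-6, 2.16e-6)  # 10x10 binned pixels for cheap stacks


@pytest.fixture()
def chi_zero():
    return ParticleModel(center=(0, 0, 250e-9), diameter=365e-9, chi_v=0.0)


def odmr(p, sensor, **kw):
    kw.setdefault("extent", EXTENT)
    kw.setdefault("oversample", 4)
    return synth_odmr_stack(p, sensor, b0_gauss=kw.pop("b0", 100.0), **kw)


class TestOdmrStack:
    def test_noiseless_uniform_field_dip_position_and_depth(self, sensor, chi_zero):
        # 5 MHz grid placed so both resonances (2590, 3150) are on-grid
        stack = odmr(chi_zero, sensor, photons_per_pixel=np.inf,
                     freqs=np.arange(2555.0, 3186.0, 5.0))
        f_minus, _ = resonance_frequencies(100.0, sensor)
        i_res = np.abs(stack.freqs - f_minus).argmin()
        # every pixel's minimum over the lower-dip half sits at the resonance
        half = stack.freqs < 2870.0
        mins = stack.frames[half].argmin(axis=0)
        assert np.all(stack.freqs[half][mins] == stack.freqs[i_res])
        depth = stack.frames[i_res]
        assert np.allclose(depth, 1.0 - DEFAULT_CONTRAST, atol=1e-4)

    def test_noiseless_limit_of_poisson_ratio(self, sensor, chi_zero):
        ideal = odmr(chi_zero, sensor, photons_per_pixel=np.inf).frames
        rms = []
        for photons in (1e3, 1e5, 1e7):
            noisy = odmr(chi_zero, sensor, photons_per_pixel=photons,
                         seed=42).frames
            rms.append(np.sqrt(np.mean((noisy - ideal) ** 2)))
        assert rms[0] > rms[1] > rms[2]
        assert rms[2] < 1e-3

    def test_fixed_seed_bit_identical(self, sensor, chi_zero):
        a = odmr(chi_zero, sensor, seed=9).frames
        b = odmr(chi_zero, sensor, seed=9).frames
        assert np.array_equal(a, b)

    def test_noiseless_stack_independent_of_seed(self, sensor, chi_zero):
        a = odmr(chi_zero, sensor, photons_per_pixel=np.inf, seed=1).frames
        b = odmr(chi_zero, sensor, photons_per_pixel=np.inf, seed=2).frames
        assert np.array_equal(a, b)

    def test_frames_positive_and_finite(self, sensor, chi_zero):
        stack = odmr(chi_zero, sensor, photons_per_pixel=300.0, seed=3)
        assert np.all(np.isfinite(stack.frames))
        assert np.all(stack.frames > 0)

    def test_background_gradient_appears_in_recovered_map(self, sensor,
                                                          chi_zero):
        from qdmpipe.odmr import analyze_stack

        gx = 2e5  # G/m -> ~0.43 G across a 2.16 um window
        stack = odmr(chi_zero, sensor, photons_per_pixel=np.inf,
                     background_gradient=(gx, 0.0))
        fmap = analyze_stack(stack, sensor)
        ny, nx = fmap.shape
        slope = np.polyfit(np.arange(nx) * fmap.pixel,
                           fmap.values[ny // 2], 1)[0]
        assert slope == pytest.approx(gx, rel=0.01)


class TestFieldSeries:
    def test_single_element_matches_plain_stack(self, sensor, chi_zero):
        series = synth_field_series(chi_zero, sensor, b0_list=[100.0], seed=5,
                                    extent=EXTENT, oversample=4,
                                    photons_per_pixel=np.inf)
        single = synth_odmr_stack(chi_zero, sensor, 100.0, seed=5,
                                  extent=EXTENT, oversample=4,
                                  photons_per_pixel=np.inf)
        assert np.array_equal(series[0].frames, single.frames)

    def test_per_stack_seeds_distinct(self, sensor, chi_zero):
        series = synth_field_series(chi_zero, sensor, b0_list=[100.0, 150.0],
                                    seed=5, extent=EXTENT, oversample=4)
        seeds = [s.meta["seed"] for s in series]
        assert len(set(seeds)) == len(seeds)

    def test_empty_field_list_rejected(self, sensor, chi_zero):
        with pytest.raises(ValueError):
            synth_field_series(chi_zero, sensor, b0_list=[])

    def test_noiseless_signal_grows_linearly_with_field(self, sensor):
        from qdmpipe.odmr import analyze_stack

        p = ParticleModel(center=(0, 0, 250e-9), diameter=365e-9, chi_v=0.053)
        series = synth_field_series(
            p, sensor, b0_list=[60.0, 120.0], photons_per_pixel=np.inf,
            extent=SMALL_EXTENT, oversample=SMALL_OVERSAMPLE)
        maps = [analyze_stack(s, sensor).values for s in series]
        ratio = np.ptp(maps[1]) / np.ptp(maps[0])
        assert ratio == pytest.approx(2.0, rel=2e-3)


class TestT1Stack:
    def make(self, sensor, particles=(), **kw):
        kw.setdefault("extent", EXTENT)
        kw.setdefault("taus", log_spaced_taus(1e-6, 1e-2, 12))
        return synth_t1_stack(list(particles), sensor, **kw)

    def test_ratio_is_unity_at_short_dark_times(self, sensor):
        stack = self.make(sensor, photons_per_pixel=np.inf,
                          taus=log_spaced_taus(1e-9, 1e-2, 15))
        assert np.allclose(stack.frames[0], 1.0, atol=1e-3)

    def test_background_pixel_closed_form(self, sensor):
        c, t1 = 0.05, 1e-3
        stack = self.make(sensor, photons_per_pixel=np.inf, contrast=c,
                          t1_background=t1, taus=np.array([1e-6, 1e-5, t1]))
        expect = 1.0 - c * (1.0 - np.exp(-1.0))
        assert stack.frames[-1, 0, 0] == pytest.approx(expect, rel=1e-9)

    def test_superparamagnetic_center_decays_faster_than_corner(self, sensor):
        p = ParticleModel(center=(0, 0, 250e-9), diameter=365e-9, chi_v=0.05,
                          superparamagnetic=True)
        stack = self.make(sensor, particles=[p], photons_per_pixel=np.inf)
        mid_tau = len(stack.taus) // 2
        ny, nx = stack.frames.shape[1:]
        assert stack.frames[mid_tau, ny // 2, nx // 2] < stack.frames[mid_tau, 0, 0]

    def test_t1_particle_cannot_exceed_background(self, sensor):
        with pytest.raises(ValueError):
            self.make(sensor, t1_background=1e-4, t1_particle=1e-3)


class TestLogSpacedTaus:
    def test_three_point_decade_spacing(self):
        taus = log_spaced_taus(1e-6, 100e-6, 3)
        assert np.allclose(taus, [1e-6, 10e-6, 100e-6], rtol=1e-12)

    def test_endpoints_exact_and_ratios_equal(self):
        taus = log_spaced_taus(3e-6, 7e-3, 9)
        assert taus[0] == pytest.approx(3e-6, rel=1e-14)
        assert taus[-1] == pytest.approx(7e-3, rel=1e-14)
        ratios = taus[1:] / taus[:-1]
        assert np.allclose(ratios, ratios[0], rtol=1e-12)

    @pytest.mark.parametrize("args", [(0, 1e-3, 5), (1e-3, 1e-6, 5),
                                      (1e-6, 1e-3, 1)])
    def test_invalid_inputs_rejected(self, args):
        with pytest.raises(ValueError):
            log_spaced_taus(*args)


class TestSpectralModels:
    def test_lorentzian_half_width_identities(self):
        w0, c, g = 2800.0, 0.02, 8.0
        assert lorentzian_dip(w0, w0, c, g) == pytest.approx(1 - c, rel=1e-14)
        assert lorentzian_dip(w0 + g, w0, c, g) == pytest.approx(1 - c / 2,
                                                                 rel=1e-14)
        assert lorentzian_dip(w0 - g, w0, c, g) == pytest.approx(1 - c / 2,
                                                                 rel=1e-14)

    def test_stretched_exponential_identities(self):
        assert stretched_exp(0.0, 1e-3, 0.05, 0.8) == pytest.approx(1.0)
        val = stretched_exp(1e-3, 1e-3, 0.05, 1.0)
        assert val == pytest.approx(1 - 0.05 * (1 - np.exp(-1)), rel=1e-12)
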