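"""Synthetic raw-measurement generator.

Emulates the two acquisition modes of the wide-field instrument so that the
whole analysis chain is testable without any recorded data:

* **ODMR stacks** — per-pixel microwave-frequency sweeps.  Each binned pixel
  carries a two-dip Lorentzian spectrum centered at the transition
  frequencies of the local total field (applied bias + particle stray
  field).  Each frequency point is the ratio of a signal exposure to a
  microwave-free reference exposure; photon shot noise enters as
  independent Poisson draws on both.
* **T1 stacks** — per-pixel stretched-exponential decays versus dark time,
  with the relaxation rate locally enhanced under particles that carry
  fluctuating (superparamagnetic) domains.

Frames are emitted already binned (the camera bins 2x2 before analysis);
noise is therefore applied per binned pixel.  The reference channel is
modeled as resonance-free unity fluorescence.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.ndimage import gaussian_filter

from .magnetostatics import AppliedField
from .sensor import (
    FWHM_TO_SIGMA,
    FieldMap,
    SensorConfig,
    centered_sweep_window,
    effective_field_image,
    resonance_frequencies,
)
from .spectra import odmr_spectrum, stretched_exp

__all__ = [
    "ODMRStack",
    "T1Stack",
    "default_freqs",
    "log_spaced_taus",
    "synth_odmr_stack",
    "synth_field_series",
    "synth_t1_stack",
]

# Assumed acquisition parameters (not measured quantities): ODMR contrast,
# Lorentzian width, photon budget per (pixel, frequency) exposure.
DEFAULT_CONTRAST = 0.02
DEFAULT_GAMMA_MHZ = 8.0
DEFAULT_PHOTONS = 1e5


@dataclass
class ODMRStack:
    """Raw ODMR sweep: frames (n_freq, rows, cols), freqs (MHz), metadata."""

    frames: np.ndarray
    freqs: np.ndarray
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] != self.freqs.size:
            raise ValueError("frames must be (n_freq, rows, cols) matching freqs")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if not np.all(np.isfinite(self.frames)) or np.any(self.frames <= 0):
            raise ValueError("frames must be finite and positive")


@dataclass
class T1Stack:
    """Raw relaxometry series: frames (n_tau, rows, cols), taus (s), metadata."""

    frames: np.ndarray
    taus: np.ndarray
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.taus = np.asarray(self.taus, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] != self.taus.size:
            raise ValueError("frames must be (n_tau, rows, cols) matching taus")
        if np.any(np.diff(self.taus) <= 0):
            raise ValueError("taus must be strictly increasing")


def log_spaced_taus(t_min: float, t_max: float, n: int) -> np.ndarray:
    """Geometric progression of dark times from t_min to t_max inclusive."""
    if not 0 < t_min < t_max:
        raise ValueError("need 0 < t_min < t_max")
    if n < 2:
        raise ValueError("n must be >= 2")
    return np.geomspace(t_min, t_max, n)


def default_freqs(b0_gauss: float, sensor: SensorConfig, n: int = 101,
                  margin: float = 30.0) -> np.ndarray:
    """Microwave sweep covering the transitions reachable at the bias field.

    If both dips fit within a practical single sweep (< 1 GHz span) the
    sweep covers both; otherwise it is centered on the lower transition, as
    done at high bias fields.
    """
    f_minus, f_plus = resonance_frequencies(b0_gauss, sensor)
    if f_plus - f_minus < 1000.0:
        return np.linspace(f_minus - margin, f_plus + margin, n)
    return np.linspace(f_minus - margin, f_minus + margin, n)


def _ratio_noise(rng, ideal, photons):
    """Poisson signal/reference ratio with mean counts photons*I and photons."""
    if not np.isfinite(photons):
        return ideal.copy()
    if photons <= 0:
        raise ValueError("photons_per_pixel must be > 0 (or inf for noiseless)")
    sig = rng.poisson(photons * ideal).astype(float)
    ref = rng.poisson(photons, size=ideal.shape).astype(float)
    ref[ref == 0] = 1.0  # a zero-photon reference exposure cannot be ratioed
    sig[sig == 0] = 1.0
    return sig / ref


def synth_odmr_stack(
    particles,
    sensor: SensorConfig,
    b0_gauss: float,
    freqs: np.ndarray | None = None,
    photons_per_pixel: float = DEFAULT_PHOTONS,
    seed: int = 0,
    extent: tuple = (6.48e-6, 6.48e-6),
    contrast: float = DEFAULT_CONTRAST,
    gamma_mhz: float = DEFAULT_GAMMA_MHZ,
    oversample: int = 8,
    moment_model: str = "fixed",
    background_gradient: tuple = (0.0, 0.0),
) -> ODMRStack:
    """Generate one raw ODMR stack for a particle scene at a bias field.

    The applied field is taken along the NV axis (the imaging
    configuration).  ``background_gradient`` adds a smooth planar NV-field
    gradient (gauss per meter along x and y, zero at the image center), as
    produced by an imperfectly homogeneous magnetizing field.  Resonances
    pushed outside the swept band by strong stray fields are produced
    anyway — recognizing them is the job of the sweep-window mask
    downstream.
    """
    applied = AppliedField.from_gauss(b0_gauss, sensor.nv_axis)
    if freqs is None:
        freqs = default_freqs(b0_gauss, sensor)
    freqs = np.asarray(freqs, dtype=float)
    signal = effective_field_image(
        particles, applied, sensor, extent=extent, oversample=oversample,
        moment_model=moment_model, mask=False,
    )
    b_total = b0_gauss + signal.values  # gauss, per binned pixel
    gx, gy = background_gradient
    if gx or gy:
        ny, nx = signal.values.shape
        pix = sensor.binned_pixel
        x = (np.arange(nx) + 0.5) * pix - nx * pix / 2.0
        y = (np.arange(ny) + 0.5) * pix - ny * pix / 2.0
        xx, yy = np.meshgrid(x, y)
        b_total = b_total + gx * xx + gy * yy
    f_minus, f_plus = resonance_frequencies(b_total, sensor)
    ideal = odmr_spectrum(
        freqs[:, None, None], f_minus[None], f_plus[None], contrast, gamma_mhz
    )
    rng = np.random.default_rng(seed)
    frames = _ratio_noise(rng, ideal, photons_per_pixel)
    meta = {
        "kind": "odmr",
        "b0_gauss": float(b0_gauss),
        "seed": int(seed),
        "photons_per_pixel": float(photons_per_pixel),
        "contrast": float(contrast),
        "gamma_mhz": float(gamma_mhz),
        "pixel_m": sensor.binned_pixel,
        "sensor": sensor.to_dict(),
    }
    return ODMRStack(frames=frames, freqs=freqs, meta=meta)


def synth_field_series(
    particles,
    sensor: SensorConfig,
    b0_list=(200.0, 600.0, 1000.0, 1400.0),
    seed: int = 0,
    **kwargs,
) -> list:
    """One ODMR stack per applied field, with distinct per-stack seeds.

    The particle magnetization is recomputed at every field.  The default
    series spans 200 to 1400 G, the range over which stray-field images
    were collected.
    """
    b0_list = list(b0_list)
    if not b0_list:
        raise ValueError("b0_list must be nonempty")
    child_seeds = np.random.SeedSequence(seed).generate_state(len(b0_list))
    stacks = []
    for b0, s in zip(b0_list, child_seeds):
        stacks.append(
            synth_odmr_stack(particles, sensor, b0, seed=int(s % (2**31)), **kwargs)
        )
    return stacks


def _t1_rate_map(particles, sensor, shape, pixel, extent):
    """Unit-amplitude enhancement profile under superparamagnetic particles."""
    ny, nx = shape
    profile = np.zeros(shape)
    x = (np.arange(nx) + 0.5) * pixel - extent[0] / 2.0
    y = (np.arange(ny) + 0.5) * pixel - extent[1] / 2.0
    xx, yy = np.meshgrid(x, y)
    any_sp = False
    for p in particles:
        if not getattr(p, "superparamagnetic", False):
            continue
        any_sp = True
        rr = np.hypot(xx - p.center[0], yy - p.center[1])
        profile[rr <= p.radius] = 1.0
    if any_sp and sensor.psf_fwhm > 0:
        sigma = sensor.psf_fwhm * FWHM_TO_SIGMA / pixel
        profile = gaussian_filter(profile, sigma, mode="reflect")
        if profile.max() > 0:
            profile /= profile.max()
    return profile


def synth_t1_stack(
    particles,
    sensor: SensorConfig,
    taus: np.ndarray | None = None,
    contrast: float = 0.05,
    t1_background: float = 1e-3,
    t1_particle: float = 2e-4,
    p_exponent: float = 1.0,
    photons_per_pixel: float = DEFAULT_PHOTONS,
    seed: int = 0,
    extent: tuple = (6.48e-6, 6.48e-6),
) -> T1Stack:
    """Generate a raw relaxometry stack.

    The per-pixel relaxation *rate* interpolates between the background
    rate and the enhanced rate ``1/t1_particle`` under each particle
    flagged superparamagnetic, with the spatial profile of a PSF-blurred
    disk (rates, not times, add for independent noise sources).
    """
    if not t1_particle <= t1_background:
        raise ValueError("t1_particle must be <= t1_background")
    if taus is None:
        taus = log_spaced_taus(1e-6, 1e-2, 20)
    taus = np.asarray(taus, dtype=float)
    pixel = sensor.binned_pixel
    shape = (int(round(extent[1] / pixel)), int(round(extent[0] / pixel)))
    profile = _t1_rate_map(particles, sensor, shape, pixel, extent)
    rate = 1.0 / t1_background + profile * (1.0 / t1_particle - 1.0 / t1_background)
    t1 = 1.0 / rate
    ideal = stretched_exp(taus[:, None, None], t1[None], contrast, p_exponent)
    rng = np.random.default_rng(seed)
    frames = _ratio_noise(rng, ideal, photons_per_pixel)
    meta = {
        "kind": "t1",
        "seed": int(seed),
        "photons_per_pixel": float(photons_per_pixel),
        "contrast": float(contrast),
        "t1_background_s": float(t1_background),
        "t1_particle_s": float(t1_particle),
        "p_exponent": float(p_exponent),
        "pixel_m": pixel,
        "sensor": sensor.to_dict(),
    }
    return T1Stack(frames=frames, taus=taus, meta=meta)
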