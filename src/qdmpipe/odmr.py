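"""ODMR image-analysis pipeline: raw sweep stack -> stray-field map -> ΔB_NV.

Stages, in acquisition order:

1. 2x2 binning of the camera frames (``bin2x2``; generator output is
   usually already binned).
2. Per-pixel Lorentzian dip fitting (``fit_odmr_pixel`` / ``fit_stack``).
3. Conversion of fitted resonance frequencies to the NV-axis field
   projection (``field_map_from_fits``): from the dip separation when both
   transitions were swept, or from the single tracked dip at high bias
   fields.
4. Background removal by the two-scale Gaussian procedure
   (``subtract_background``).
5. Scalar stray-field amplitude ΔB_NV from a three-pixel-wide line cut
   through the signal maximum fitted with a double Gaussian
   (``linecut_delta_b``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import curve_fit

from .sensor import FieldMap, SensorConfig, resonance_frequencies
from .spectra import lorentzian_dip
from .synth import ODMRStack

__all__ = [
    "PixelFit",
    "LineCutResult",
    "bin2x2",
    "fit_odmr_pixel",
    "fit_stack",
    "field_map_from_fits",
    "subtract_background",
    "auto_signal_mask",
    "linecut_delta_b",
]

log = logging.getLogger(__name__)


@dataclass
class PixelFit:
    """Single-dip Lorentzian fit result at one pixel."""

    omega0: float  # MHz
    contrast: float
    gamma_width: float  # MHz
    residual: float
    valid: bool = True


@dataclass
class LineCutResult:
    """Line-cut profile and its double-Gaussian ΔB_NV metric."""

    positions: np.ndarray  # m, along the cut
    profile: np.ndarray  # G
    fit_params: dict
    delta_b: float  # G, peak-to-peak of the fitted curve
    delta_b_err: float  # G, SD of background pixels
    axis: int = 1  # image axis the cut runs along
    fallback: bool = False  # raw max-min used instead of the fit


def bin2x2(frames: np.ndarray) -> np.ndarray:
    """Mean-bin the two trailing (image) axes by a factor of 2.

    Odd trailing rows/columns are dropped (logged), matching camera
    behavior for odd readout sizes.
    """
    frames = np.asarray(frames, dtype=float)
    ny, nx = frames.shape[-2:]
    if ny % 2 or nx % 2:
        log.info("bin2x2: dropping odd trailing row/column (%d, %d)", ny, nx)
        frames = frames[..., : ny - ny % 2, : nx - nx % 2]
        ny, nx = frames.shape[-2:]
    shape = frames.shape[:-2] + (ny // 2, 2, nx // 2, 2)
    return frames.reshape(shape).mean(axis=(-1, -3))


def fit_odmr_pixel(freqs, intensities, window=None) -> PixelFit:
    """Least-squares fit of a single Lorentzian dip to one pixel's spectrum.

    ``window`` restricts the fit to a frequency sub-band (used to isolate
    one of the two dips).  Initialization: resonance at the sample minimum,
    contrast from the dip depth, width from a half-depth crossing scan.
    Non-convergence or a resonance pinned to the band edge flags the pixel
    invalid.
    """
    freqs = np.asarray(freqs, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if window is not None:
        sel = (freqs >= window[0]) & (freqs <= window[1])
        freqs, intensities = freqs[sel], intensities[sel]
    if freqs.size < 5:
        raise ValueError("need at least 5 samples spanning the dip")
    i_min = int(np.argmin(intensities))
    omega0 = freqs[i_min]
    baseline = np.median(intensities)
    depth = max(baseline - intensities[i_min], 1e-6)
    half = intensities[i_min] + depth / 2.0
    below = np.flatnonzero(intensities <= half)
    if below.size >= 2:
        gamma0 = max((freqs[below[-1]] - freqs[below[0]]) / 2.0, np.diff(freqs).min())
    else:
        gamma0 = 4.0 * np.diff(freqs).mean()
    try:
        popt, _ = curve_fit(
            lorentzian_dip,
            freqs,
            intensities,
            p0=(omega0, depth, gamma0),
            bounds=([freqs[0], 0.0, 1e-6], [freqs[-1], 1.0, freqs[-1] - freqs[0]]),
            xtol=1e-12,
            ftol=1e-12,
            maxfev=2000,
        )
    except RuntimeError:
        return PixelFit(np.nan, np.nan, np.nan, np.inf, valid=False)
    resid = float(np.sqrt(np.mean((lorentzian_dip(freqs, *popt) - intensities) ** 2)))
    step = np.diff(freqs).mean()
    edge = popt[0] <= freqs[0] + step or popt[0] >= freqs[-1] - step
    return PixelFit(float(popt[0]), float(popt[1]), float(popt[2]), resid,
                    valid=not edge)


def _dip_windows(stack: ODMRStack, sensor: SensorConfig):
    """Frequency windows isolating the tracked dip(s) in a stack's sweep."""
    b0 = stack.meta.get("b0_gauss", 0.0)
    f_minus, f_plus = resonance_frequencies(b0, sensor)
    lo, hi = stack.freqs[0], stack.freqs[-1]
    windows = {}
    if f_plus - f_minus < (hi - lo):
        mid = 0.5 * (f_minus + f_plus)
        if f_minus >= lo:
            windows["minus"] = (lo, mid)
        if f_plus <= hi:
            windows["plus"] = (mid, hi)
    else:
        for name, f in (("minus", f_minus), ("plus", f_plus)):
            if lo <= f <= hi:
                windows[name] = (lo, hi)
    if not windows:
        raise ValueError("no tracked transition lies inside the swept band")
    return windows


def fit_stack(stack: ODMRStack, sensor: SensorConfig | None = None,
              engine: str = "vectorized") -> dict:
    """Per-pixel dip fits for every tracked transition in a stack.

    Returns ``{dip_name: {"omega0": 2-D array, "contrast": ..., "gamma":
    ..., "valid": bool array}}``; unconverged pixels are NaN/invalid.
    ``engine="vectorized"`` fits all pixels at once by damped Gauss–Newton
    (same Lorentzian model); ``engine="scipy"`` loops ``curve_fit`` over
    pixels.
    """
    sensor = sensor or SensorConfig.from_dict(stack.meta.get("sensor", {}))
    windows = _dip_windows(stack, sensor)
    _, ny, nx = stack.frames.shape
    out = {}
    for name, window in windows.items():
        if engine == "vectorized":
            from .spectra import fit_lorentzian_grid

            sel = (stack.freqs >= window[0]) & (stack.freqs <= window[1])
            omega0, contrast, gamma, valid = fit_lorentzian_grid(
                stack.freqs[sel], stack.frames[sel])
            omega0 = np.where(valid, omega0, np.nan)
            contrast = np.where(valid, contrast, np.nan)
            gamma = np.where(valid, gamma, np.nan)
        elif engine == "scipy":
            omega0 = np.full((ny, nx), np.nan)
            contrast = np.full((ny, nx), np.nan)
            gamma = np.full((ny, nx), np.nan)
            valid = np.zeros((ny, nx), dtype=bool)
            for iy in range(ny):
                for ix in range(nx):
                    fit = fit_odmr_pixel(stack.freqs, stack.frames[:, iy, ix],
                                         window)
                    if fit.valid:
                        omega0[iy, ix] = fit.omega0
                        contrast[iy, ix] = fit.contrast
                        gamma[iy, ix] = fit.gamma_width
                        valid[iy, ix] = True
        else:
            raise ValueError(f"unknown engine {engine!r}")
        out[name] = {"omega0": omega0, "contrast": contrast, "gamma": gamma,
                     "valid": valid}
    return out


def field_map_from_fits(
    fits: dict,
    sensor: SensorConfig,
    pixel: float,
    b0_gauss: float | None = None,
) -> FieldMap:
    """NV-axis field map (gauss) from per-pixel dip fits.

    With both dips fitted, ``B = (f_plus - f_minus) / (2 gamma)``.  With a
    single tracked dip (high bias field), the field follows from that dip
    alone, using the nominal bias to pick the branch of
    ``f_minus = |D - gamma B|``.  Pixels lacking a valid fit are NaN.
    """
    g = sensor.gyromagnetic_ratio
    d0 = sensor.zero_field_splitting
    if "minus" in fits and "plus" in fits:
        values = (fits["plus"]["omega0"] - fits["minus"]["omega0"]) / (2.0 * g)
        values[~(fits["minus"]["valid"] & fits["plus"]["valid"])] = np.nan
    elif "plus" in fits:
        values = (fits["plus"]["omega0"] - d0) / g
        values[~fits["plus"]["valid"]] = np.nan
    elif "minus" in fits:
        if b0_gauss is None:
            raise ValueError("single-dip conversion needs the nominal bias field")
        if b0_gauss * g >= d0:  # beyond the level crossing: f- = gB - D
            values = (fits["minus"]["omega0"] + d0) / g
        else:
            values = (d0 - fits["minus"]["omega0"]) / g
        values[~fits["minus"]["valid"]] = np.nan
    else:
        raise ValueError("fits must contain 'minus' and/or 'plus'")
    return FieldMap(values, pixel)


def analyze_stack(stack: ODMRStack, sensor: SensorConfig | None = None) -> FieldMap:
    """Convenience: fit a stack and return the stray-field map (bias removed)."""
    sensor = sensor or SensorConfig.from_dict(stack.meta.get("sensor", {}))
    b0 = stack.meta.get("b0_gauss", None)
    fits = fit_stack(stack, sensor)
    fmap = field_map_from_fits(fits, sensor, stack.meta.get("pixel_m", sensor.binned_pixel),
                               b0_gauss=b0)
    if b0 is not None:
        fmap.values = fmap.values - b0
    return fmap


def _nan_gaussian(values: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian blur ignoring NaNs (normalized convolution, reflective edges)."""
    finite = np.isfinite(values)
    if finite.all():
        return gaussian_filter(values, sigma, mode="reflect")
    num = gaussian_filter(np.where(finite, values, 0.0), sigma, mode="reflect")
    den = gaussian_filter(finite.astype(float), sigma, mode="reflect")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def subtract_background(
    fmap: FieldMap,
    signal_mask: np.ndarray | None = None,
    sigma_coarse: float = 50.0,
    sigma_fine: float = 25.0,
):
    """Two-scale Gaussian background removal.

    (1) blur the map with a ``sigma_coarse``-pixel kernel to form a coarse
    background; (2) replace the pixels under the signal mask by that coarse
    background, so the signal does not leak into the estimate; (3) blur the
    replaced image with a ``sigma_fine``-pixel kernel to form the
    background.  The signal is the original minus the background.

    Returns ``(signal_map, background_map)``.  Masked (NaN) cells
    propagate; a signal mask covering more than half the map triggers a
    warning.
    """
    values = fmap.values
    if signal_mask is not None:
        signal_mask = np.asarray(signal_mask, dtype=bool)
        if signal_mask.shape != values.shape:
            raise ValueError("signal_mask shape mismatch")
        if signal_mask.mean() > 0.5:
            warnings.warn("signal mask covers more than half the map")
    coarse = _nan_gaussian(values, sigma_coarse)
    if signal_mask is None:
        replaced = values
    else:
        replaced = np.where(signal_mask, coarse, values)
    background = _nan_gaussian(replaced, sigma_fine)
    signal = values - background
    return (
        FieldMap(signal, fmap.pixel, fmap.origin),
        FieldMap(background, fmap.pixel, fmap.origin),
    )


def auto_signal_mask(fmap: FieldMap, psf_fwhm: float = 450e-9,
                     sigma_fine: float = 25.0) -> np.ndarray:
    """Disk mask of radius ``2 * psf_fwhm`` at the high-pass-residual peak."""
    resid = fmap.values - _nan_gaussian(fmap.values, sigma_fine)
    resid = np.where(np.isfinite(resid), np.abs(resid), -np.inf)
    iy, ix = np.unravel_index(int(np.argmax(resid)), resid.shape)
    ny, nx = fmap.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    r_pix = 2.0 * psf_fwhm / fmap.pixel
    return (yy - iy) ** 2 + (xx - ix) ** 2 <= r_pix**2


def _double_gaussian(x, offset, a1, c1, w1, a2, c2, w2):
    return (
        offset
        + a1 * np.exp(-0.5 * ((x - c1) / w1) ** 2)
        - a2 * np.exp(-0.5 * ((x - c2) / w2) ** 2)
    )


def _fit_cut(positions, profile):
    """Double-Gaussian fit of one cut; returns (p2p, params) or None."""
    finite = np.isfinite(profile)
    x, y = positions[finite], profile[finite]
    if x.size < 8:
        return None
    offset0 = float(np.median(y))
    i_max, i_min = int(np.argmax(y)), int(np.argmin(y))
    a1_0 = max(y[i_max] - offset0, 1e-12)
    a2_0 = max(offset0 - y[i_min], 1e-12)
    span = x[-1] - x[0]
    w0 = span / 12.0
    p0 = (offset0, a1_0, x[i_max], w0, a2_0, x[i_min], w0)
    big = 10.0 * (np.abs(y - offset0).max() + 1e-12)
    # lobes live inside the window at roughly PSF scale: bounding the
    # centers to the window and the widths to a third of it keeps the fit
    # from canceling two huge offset Gaussians against each other on noise
    pad = span / 20.0
    bounds = (
        [-np.inf, 0.0, x[0] - pad, span / 200.0, 0.0, x[0] - pad, span / 200.0],
        [np.inf, big, x[-1] + pad, span / 3.0, big, x[-1] + pad, span / 3.0],
    )
    try:
        popt, _ = curve_fit(_double_gaussian, x, y, p0=p0, bounds=bounds,
                            xtol=1e-14, ftol=1e-14, gtol=1e-14, maxfev=8000)
    except RuntimeError:
        return None
    if popt[3] < span / 150.0 or popt[6] < span / 150.0:
        return None  # degenerate widths
    dense = np.linspace(x[0], x[-1], 50 * x.size)
    curve = _double_gaussian(dense, *popt)

    def d_curve(t):
        _, a1, c1, w1, a2, c2, w2 = popt
        g1 = a1 * np.exp(-0.5 * ((t - c1) / w1) ** 2)
        g2 = a2 * np.exp(-0.5 * ((t - c2) / w2) ** 2)
        d1 = -g1 * (t - c1) / w1**2 + g2 * (t - c2) / w2**2
        d2 = (g1 * (((t - c1) / w1**2) ** 2 - 1 / w1**2)
              - g2 * (((t - c2) / w2**2) ** 2 - 1 / w2**2))
        return d1, d2

    def refine(idx):
        # Newton polish of the dense-grid extremum (smooth in the params)
        t = dense[idx]
        if 0 < idx < dense.size - 1:
            for _ in range(4):
                d1, d2 = d_curve(t)
                if d2 == 0:
                    break
                step = d1 / d2
                if abs(step) > (dense[1] - dense[0]):
                    break
                t = t - step
            t = min(max(t, x[0]), x[-1])
        return _double_gaussian(t, *popt)

    hi = refine(int(np.argmax(curve)))
    lo = refine(int(np.argmin(curve)))
    return float(hi - lo), popt


def linecut_delta_b(
    fmap: FieldMap,
    mask: np.ndarray | None = None,
    width: int = 3,
) -> LineCutResult:
    """ΔB_NV from a three-pixel-wide line cut through the signal maximum.

    Cuts along both image axes through the pixel of maximum ``|signal|``
    are fitted with an offset plus one positive and one negative Gaussian;
    the axis giving the larger fitted peak-to-peak is retained (dipolar
    lobes align with the unknown in-plane field direction).  ``delta_b`` is
    the max-minus-min of the fitted curve; ``delta_b_err`` is the SD of the
    background pixels (outside ``mask`` when given).  Degenerate fits fall
    back to the raw max-minus-min of the profile, with a warning.
    """
    values = fmap.values
    search = np.where(np.isfinite(values), np.abs(values), -np.inf)
    if mask is not None:
        search = np.where(mask, search, -np.inf)
    if not np.any(np.isfinite(values)):
        raise ValueError("field map has no valid pixels")
    iy, ix = np.unravel_index(int(np.argmax(search)), values.shape)
    ny, nx = values.shape
    half = width // 2

    candidates = []
    # cut along x (axis=1): average rows iy-half..iy+half
    rows = values[max(0, iy - half) : iy + half + 1, :]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        prof_x = np.nanmean(rows, axis=0)
    pos_x = (np.arange(nx) + 0.5) * fmap.pixel
    candidates.append((1, pos_x, prof_x))
    cols = values[:, max(0, ix - half) : ix + half + 1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        prof_y = np.nanmean(cols, axis=1)
    pos_y = (np.arange(ny) + 0.5) * fmap.pixel
    candidates.append((0, pos_y, prof_y))

    if mask is not None:
        bg = values[~mask]
    else:
        bg = values
    bg = bg[np.isfinite(bg)]
    err = float(np.std(bg)) if bg.size else np.nan

    best = None
    for axis, pos, prof in candidates:
        res = _fit_cut(pos, prof)
        if res is None:
            continue
        p2p, popt = res
        if best is None or p2p > best[0]:
            best = (p2p, popt, axis, pos, prof)
    if best is None:
        axis, pos, prof = candidates[0]
        finite = prof[np.isfinite(prof)]
        p2p = float(finite.max() - finite.min()) if finite.size else 0.0
        warnings.warn("double-Gaussian fit degenerate; using raw max-min")
        return LineCutResult(pos, prof, {}, p2p, err, axis=axis, fallback=True)
    p2p, popt, axis, pos, prof = best
    params = dict(zip(
        ["offset", "amp_pos", "center_pos", "width_pos", "amp_neg",
         "center_neg", "width_neg"], map(float, popt)))
    return LineCutResult(pos, prof, params, p2p, err, axis=axis)
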