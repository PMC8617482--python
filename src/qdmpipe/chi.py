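"""Susceptibility inference from stray-field amplitude versus applied field.

The measured observable is xi, the slope of the line-cut peak-to-peak
stray-field amplitude ΔB_NV against the applied bias field B0.  xi is
dimensionless and proportional to the particle's volume susceptibility,
but the proportionality depends on unobserved geometry (particle height
above the NV plane, diameter).  Bounds on chi_v are therefore obtained by
forward-simulating xi over a (chi, height) grid and intersecting the
measured xi ± 1 SD with the simulated surface, exactly as one reads
contour lines off the simulation map.

The anisotropy contribution to the xi scatter is quantified by a Monte
Carlo over uniformly random easy-axis orientations of an otherwise
identical particle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np

from .magnetostatics import MU0, sample_easy_axes
from .odmr import linecut_delta_b
from .sensor import (
    FieldMap,
    SensorConfig,
    blur_bin_fine,
    centered_sweep_window,
    fine_projection_operator,
    spectral_field_image,
    sweep_mask,
)

__all__ = [
    "XiEstimate",
    "ChiBounds",
    "fit_xi",
    "simulate_xi",
    "xi_grid",
    "bounds_from_grid",
    "chi_bounds",
    "anisotropy_rel_error",
    "combine_cohorts",
    "default_height_grid",
]

#: Bias field used for forward xi simulations (the magnetizing field of the
#: imaging experiments); the simulated observable is linear in B0, so any
#: single field determines the slope.
DEFAULT_B0_GAUSS = 1400.0

#: Analysis window for simulated images: 30 x 30 binned pixels (~6.5 um),
#: comfortably containing the blurred dipolar pattern.
DEFAULT_EXTENT = (6.48e-6, 6.48e-6)

DEFAULT_DIAMETER = 365e-9
DEFAULT_PACKING = 0.7

# Printed per-cohort xi averages: (mean, SD, particle count).
COHORTS = {"lagena": (3.5e-4, 1.5e-4, 4), "basilar_papilla": (2.3e-4, 0.9e-4, 6)}


@dataclass
class XiEstimate:
    xi: float
    xi_err: float
    points: np.ndarray  # (n, 3): B0 (G), delta_b (G), err (G)
    intercept: float


@dataclass
class ChiBounds:
    chi_lo: float
    chi_hi: float
    grid: dict  # {"chi": ..., "height": ..., "xi": (n_chi, n_height)}
    matched_contours: dict  # target xi -> chi(height) arrays
    warnings: list = dc_field(default_factory=list)


def fit_xi(points) -> XiEstimate:
    """Weighted least-squares line ΔB_NV = xi * B0 + intercept.

    ``points`` is an iterable of (B0_gauss, delta_b_gauss, err_gauss); a
    nonpositive or missing error means equal weighting.  ``xi_err`` comes
    from the parameter covariance (known-error convention when errors are
    supplied, residual-scaled otherwise).
    """
    pts = np.asarray([tuple(p) if len(p) == 3 else (p[0], p[1], 0.0) for p in points],
                     dtype=float)
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 points")
    b0, db, err = pts.T
    if np.ptp(b0) == 0:
        raise ValueError("all applied fields equal: slope is undetermined")
    use_w = np.all(err > 0)
    w = 1.0 / err**2 if use_w else np.ones_like(b0)
    X = np.column_stack([b0, np.ones_like(b0)])
    XtW = X.T * w
    cov = np.linalg.inv(XtW @ X)
    beta = cov @ (XtW @ db)
    if not use_w:
        resid = db - X @ beta
        dof = max(len(b0) - 2, 1)
        cov = cov * float(resid @ resid) / dof
    return XiEstimate(xi=float(beta[0]), xi_err=float(np.sqrt(cov[0, 0])),
                      points=pts, intercept=float(beta[1]))


def _sim_sensor(sensor: SensorConfig | None, b0: float) -> SensorConfig:
    """Sensor with the sweep window re-centered on the tracked dip at b0."""
    sensor = sensor or SensorConfig()
    lo, hi = sensor.sweep_window
    from .sensor import resonance_frequencies

    f_minus, f_plus = resonance_frequencies(b0, sensor)
    if (lo <= f_minus <= hi) or (lo <= f_plus <= hi):
        return sensor
    return sensor.with_window(centered_sweep_window(b0, sensor=sensor))


_OP_CACHE: dict = {}


def _cached_fine_operator(height, diameter, sensor, extent, oversample, voxel_pitch):
    """Fine-raster projection kernel, cached per geometry (the costly part)."""
    key = (round(height, 15), round(diameter, 15), tuple(np.round(sensor.nv_axis, 12)),
           sensor.raw_pixel, sensor.binning, tuple(extent),
           int(oversample), voxel_pitch)
    if key not in _OP_CACHE:
        if len(_OP_CACHE) > 32:
            _OP_CACHE.clear()
        _OP_CACHE[key] = fine_projection_operator(
            height, diameter, sensor, extent=extent, oversample=int(oversample),
            voxel_pitch=voxel_pitch)
    return _OP_CACHE[key]


def _fine_blackout(fine_G, b0, sensor):
    """True when extracting every NV's resonance would need a wider sweep.

    Evaluated on the unblurred fine raster: this is the "blacked out"
    criterion of the forward simulation maps — a parameter set is excluded
    when the resonances of *all* pixels of its simulated ODMR image cannot
    be extracted within the sweep window.
    """
    valid = sweep_mask(b0 + fine_G, sensor, b0_gauss=b0)
    return not valid.all()


def _measured_map(fine_op, m, b0, sensor, oversample, response,
                  blackout_check: bool = False):
    """Measured stray-field map (gauss, NaN = clipped) for moment ``m``."""
    fine_G = (fine_op @ m) * 1e4
    if blackout_check and _fine_blackout(fine_G, b0, sensor):
        ny, nx = fine_G.shape
        ov = int(oversample)
        return np.full((ny // ov, nx // ov), np.nan)
    if response == "spectral":
        return spectral_field_image(fine_G, b0, sensor, int(oversample))
    if response != "field":
        raise ValueError(f"unknown response model {response!r}")
    sig = blur_bin_fine(fine_G, sensor, int(oversample))
    valid = sweep_mask(b0 + sig, sensor, b0_gauss=b0)
    return np.where(valid, sig, np.nan)


def _moment_for_chi(chi_v, diameter, packing, b0, direction):
    v = packing * (np.pi / 6.0) * diameter**3
    return chi_v * v * (b0 * 1e-4) / MU0 * np.asarray(direction)


def simulate_xi(
    chi_v: float,
    height: float,
    diameter: float = DEFAULT_DIAMETER,
    sensor: SensorConfig | None = None,
    b0_list=None,
    packing: float = DEFAULT_PACKING,
    extent: tuple = DEFAULT_EXTENT,
    oversample: int = 8,
    voxel_pitch: float | None = None,
    response: str = "spectral",
) -> float:
    """Noiseless forward-simulated xi for one (chi, height) parameter set.

    Runs the effective-field image and the line-cut amplitude extraction at
    each bias field and fits the slope.  The default is the single-field
    path ``xi = delta_b / B0`` at the 1400 G magnetizing field (for the
    ``"field"`` response model the observable is exactly linear in B0, so
    one field determines the slope; the ``"spectral"`` model is evaluated
    at the measurement field for the same reason the experiment was).
    Returns NaN (the "blacked out" sentinel) when the sweep window rejects
    the whole image.
    """
    single = b0_list is None
    b0_list = [DEFAULT_B0_GAUSS] if single else list(b0_list)
    pts = []
    for b0 in b0_list:
        s = _sim_sensor(sensor, b0)
        fine_op = _cached_fine_operator(height, diameter, s, extent, oversample,
                                        voxel_pitch)
        m = _moment_for_chi(chi_v, diameter, packing, b0, s.nv_axis)
        vals = _measured_map(fine_op, m, b0, s, oversample, response)
        if not np.any(np.isfinite(vals)):
            return np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cut = linecut_delta_b(FieldMap(vals, s.binned_pixel))
        pts.append((b0, cut.delta_b, 0.0))
    if single:
        return pts[0][1] / pts[0][0]
    return fit_xi(pts).xi


def default_height_grid(diameter: float = DEFAULT_DIAMETER,
                        sensor: SensorConfig | None = None,
                        section_thickness: float = 500e-9,
                        n: int = 10) -> np.ndarray:
    """Particle-center heights (NV plane to center) swept for the inversion.

    The center must sit at least one radius above the diamond surface;
    the sweep extends over the full tissue-section thickness (sections
    need not contact the diamond, so centers up to ~one section thickness
    above the surface are physical).  The NV implant depth adds to both
    ends.
    """
    sensor = sensor or SensorConfig()
    r = diameter / 2.0
    lo = r + sensor.implant_depth
    hi = section_thickness + sensor.implant_depth
    return np.linspace(lo, hi, n)


def xi_grid(
    chi_values,
    heights,
    diameter: float = DEFAULT_DIAMETER,
    sensor: SensorConfig | None = None,
    b0: float = DEFAULT_B0_GAUSS,
    packing: float = DEFAULT_PACKING,
    extent: tuple = DEFAULT_EXTENT,
    oversample: int = 8,
    voxel_pitch: float | None = None,
    response: str = "spectral",
) -> dict:
    """Forward-simulated xi over a (chi, height) grid at one bias field.

    One fine-raster geometric kernel per height serves every chi (the
    stray field is linear in the moment); the measured image is then
    re-evaluated per chi.  Grid cells for which extracting every NV's
    resonance would require a wider microwave sweep come back NaN — the
    "blacked out" high-chi / low-height corner of the inversion map.
    """
    chi_values = np.asarray(chi_values, dtype=float)
    heights = np.asarray(heights, dtype=float)
    s = _sim_sensor(sensor, b0)
    xi = np.full((chi_values.size, heights.size), np.nan)
    for j, h in enumerate(heights):
        fine_op = _cached_fine_operator(h, diameter, s, extent, oversample,
                                        voxel_pitch)
        for i, chi in enumerate(chi_values):
            m = _moment_for_chi(chi, diameter, packing, b0, s.nv_axis)
            vals = _measured_map(fine_op, m, b0, s, oversample, response,
                                 blackout_check=True)
            if not np.any(np.isfinite(vals)):
                continue
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cut = linecut_delta_b(FieldMap(vals, s.binned_pixel))
            except ValueError:
                continue
            xi[i, j] = cut.delta_b / b0
    return {"chi": chi_values, "height": heights, "xi": xi, "b0": b0,
            "diameter": diameter, "packing": packing, "response": response}


def _contour_chi(chi, xi_col, target):
    """Interpolated chi where the xi(chi) column first crosses target.

    xi grows with chi over the physical (unclipped) range; once the sweep
    window starts clipping the pattern the column may sag or vanish, so
    only the strictly increasing prefix is used for the crossing.
    """
    ok = np.isfinite(xi_col)
    if ok.sum() < 2:
        return np.nan
    c, x = chi[ok], xi_col[ok]
    keep = x >= np.maximum.accumulate(x)  # strictly increasing prefix points
    c, x = c[keep], x[keep]
    # drop duplicates that accumulate at the running max
    uniq = np.concatenate([[True], np.diff(x) > 0])
    c, x = c[uniq], x[uniq]
    if x.size < 2 or target < x.min() or target > x.max():
        return np.nan
    # interpolate in log-chi
    return float(np.exp(np.interp(target, x, np.log(c))))


def bounds_from_grid(grid: dict, xi_mean: float, xi_sd: float) -> ChiBounds:
    """Susceptibility bounds from a precomputed xi(chi, height) grid.

    ``chi_lo`` is the smallest chi on the ``xi = xi_mean + xi_sd`` contour,
    ``chi_hi`` the largest chi on the ``xi = xi_mean - xi_sd`` contour,
    both over unmasked grid cells.  An empty contour collapses the bound to
    the grid edge with a warning recorded on the result.
    """
    chi, heights, xi = grid["chi"], grid["height"], grid["xi"]
    notes = []
    contours = {}
    for label, target in (("upper_contour", xi_mean + xi_sd),
                          ("mean_contour", xi_mean),
                          ("lower_contour", xi_mean - xi_sd)):
        contours[label] = np.array([_contour_chi(chi, xi[:, j], target)
                                    for j in range(heights.size)])
    up = contours["upper_contour"]
    lo_c = contours["lower_contour"]
    if np.any(np.isfinite(up)):
        chi_lo = float(np.nanmin(up))
    else:
        chi_lo = float(chi[0])
        notes.append("xi_mean + sd contour outside the grid; chi_lo set to grid edge")
        warnings.warn(notes[-1])
    if np.any(np.isfinite(lo_c)):
        chi_hi = float(np.nanmax(lo_c))
    else:
        chi_hi = float(chi[-1])
        notes.append("xi_mean - sd contour outside the grid; chi_hi set to grid edge")
        warnings.warn(notes[-1])
    if chi_lo > chi_hi:
        chi_lo, chi_hi = chi_hi, chi_lo
    return ChiBounds(chi_lo=chi_lo, chi_hi=chi_hi, grid=grid,
                     matched_contours=contours, warnings=notes)


def chi_bounds(
    xi_mean: float,
    xi_sd: float,
    diameter: float = DEFAULT_DIAMETER,
    sensor: SensorConfig | None = None,
    chi_grid=None,
    height_grid=None,
    **kwargs,
) -> ChiBounds:
    """Forward-sweep inversion of a measured xi into chi_v bounds."""
    if chi_grid is None:
        chi_grid = np.geomspace(1e-3, 1.0, 40)
    if height_grid is None:
        height_grid = default_height_grid(diameter, sensor)
    grid = xi_grid(chi_grid, height_grid, diameter=diameter, sensor=sensor, **kwargs)
    return bounds_from_grid(grid, xi_mean, xi_sd)


def combine_cohorts(cohorts: dict = COHORTS):
    """Count-weighted combination of per-cohort xi averages.

    Returns (mean, sd): the particle-count-weighted mean of the cohort
    means and the likewise-pooled SD.
    """
    means = np.array([v[0] for v in cohorts.values()])
    sds = np.array([v[1] for v in cohorts.values()])
    ns = np.array([v[2] for v in cohorts.values()], dtype=float)
    mean = float((ns * means).sum() / ns.sum())
    sd = float(np.sqrt((ns * sds**2).sum() / ns.sum()))
    return mean, sd


def anisotropy_rel_error(
    n: int = 300,
    seed: int = 0,
    chi_v: float = 0.053,
    diameter: float = DEFAULT_DIAMETER,
    height: float = 207.5e-9,
    sensor: SensorConfig | None = None,
    b0: float = DEFAULT_B0_GAUSS,
    packing: float = DEFAULT_PACKING,
    extent: tuple = DEFAULT_EXTENT,
    oversample: int = 8,
    voxel_pitch: float | None = None,
    moment_model: str = "fixed",
    response: str = "spectral",
    return_amplitudes: bool = False,
):
    """SD/mean of the stray-field amplitude over random easy-axis directions.

    Draws ``n`` uniformly distributed easy axes; for each, the uniaxially
    magnetized particle's effective field image is simulated (every other
    parameter held fixed) and the line-cut peak-to-peak amplitude
    extracted.  The returned ratio is the relative xi error attributable to
    unknown magnetic anisotropy.  ``moment_model`` follows
    :func:`qdmpipe.magnetostatics.induced_moment`; isotropic particles have
    no orientation dependence, so the ratio is zero by definition there.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    s = _sim_sensor(sensor, b0)
    fine_op = _cached_fine_operator(height, diameter, s, extent, oversample,
                                    voxel_pitch)
    v = packing * (np.pi / 6.0) * diameter**3
    m_scale = chi_v * v * (b0 * 1e-4) / MU0
    nhat = np.asarray(s.nv_axis)
    axes = sample_easy_axes(n, seed)
    amps = np.empty(n)
    for i, e in enumerate(axes):
        if moment_model == "projection":
            m = m_scale * float(nhat @ e) * e
        elif moment_model == "fixed":
            m = m_scale * e
        elif moment_model == "isotropic":  # no easy axis: m always along B0
            m = m_scale * nhat
        else:
            raise ValueError(f"unknown moment_model {moment_model!r}")
        vals = _measured_map(fine_op, m, b0, s, oversample, response)
        if not np.any(np.isfinite(vals)):
            amps[i] = np.nan
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cut = linecut_delta_b(FieldMap(vals, s.binned_pixel))
        amps[i] = cut.delta_b
    amps = amps[np.isfinite(amps)]
    if amps.size < 2:
        raise ZeroDivisionError("too few valid amplitudes; ratio undefined")
    mean = amps.mean()
    if abs(mean) < 1e-30:
        raise ZeroDivisionError("mean amplitude is zero; ratio undefined")
    ratio = float(amps.std() / mean)
    if return_amplitudes:
        return ratio, amps
    return ratio
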