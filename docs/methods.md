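# Methods

This note documents the physical models, the defaults and why they were
chosen, the numerics, and the known limits of what the synthetic studies
can show. Internal units are SI (tesla, meter, A·m², second); gauss and
MHz appear only at I/O boundaries (1 G = 10⁻⁴ T).

## Magnetostatic forward model

A particle is a sphere of diameter *d* whose magnetic mineral occupies a
packing fraction φ of its volume (default 0.7 — loosely infilled iron
organelles), with dimensionless volume susceptibility χᵥ. In a uniform
applied field **B₀** it carries the induced moment

    m = χᵥ V B₀ / μ₀,    V = φ (π/6) d³.

Two uniaxial (easy-axis) variants are implemented in addition to the
isotropic response:

* `fixed` (default): the moment keeps the full magnitude χᵥVB₀/μ₀ and is
  rotated onto the easy axis — the reading in which the applied field
  strength multiplies a free magnetization direction. The easy-axis Monte
  Carlo below discriminates the two variants empirically and supports this
  one.
* `projection`: the moment magnitude is scaled by the cosine of the
  axis–field angle (zero transverse susceptibility); it vanishes for a
  perpendicular axis and is the stricter upper bound on orientation-induced
  variation.

The stray field is the superposition of identical point dipoles placed on
a cubic grid inside the sphere. The default grid pitch is 20 nm: at the
standoffs relevant here (≥ 197.5 nm to the sphere center) the cloud agrees
with the single equivalent dipole to better than 1 % at five diameters and
0.1 % at ten diameters (tested), and the sum of voxel moments equals the
induced moment exactly by construction. Evaluating the field at a dipole
position raises an error rather than returning a singular value.

## Instrument response

The sensor model maps a physical stray field to the image the microscope
reports. Geometry: the diamond surface normal is z, the NV axis is
(1,1,1)/√3 (a ⟨100⟩-cut chip), the NV layer is a delta plane 15 nm below
the surface (typical of 4 keV ¹⁵N implantation), and the applied field is
aligned with the NV axis. Particle heights are NV-plane-to-center
distances. Optics: Gaussian PSF of 450 nm FWHM; camera pixels of 108 nm
back-projected, binned 2×2 to 216 nm. The microwave sweep window is
configurable; at high bias fields it is re-centered on the one reachable
transition (`centered_sweep_window`, ±50 MHz by default, i.e. a ±17.9 G
dynamic range).

The field is sampled on a fine raster at the NV plane. The raster pitch is
`binned_pixel / oversample`; simulations here use oversample 6–8 (27–36 nm)
after checking convergence (the line-cut amplitude changes by < 1 % between
oversample 4 and 16). Two response models are provided:

* **field** — project onto the NV axis, blur with the PSF, area-average to
  binned pixels, then mask pixels whose resonances leave the sweep window.
  This model is exactly linear in the particle moments, which the fast
  susceptibility sweeps and several invariant tests rely on.
* **spectral** — build, at every fine-raster point, the Lorentzian ODMR dip
  at the local resonance; blur and bin the *spectra*; then fit a single
  Lorentzian per binned pixel, exactly as the data pipeline does. When the
  field varies strongly inside one diffraction spot, the composite spectrum
  is a mixture dominated by the majority (background) component, and the
  fitted dip tracks that component rather than the field average: sharp
  field extremes are compressed well below their blurred-field value (for
  the reference particle below, the amplitude drops from 2.15 G to 1.50 G).
  This is the response the instrument actually has to sub-diffraction
  sources, at the cost of strict linearity; the per-pixel fits use a
  vectorized damped Gauss–Newton solver (verified against scipy's
  `curve_fit` on the same model).

Quantities compared with measured data (the ξ grid inversion, the easy-axis
Monte Carlo) use the spectral model; synthetic raw-data generation and the
generator↔pipeline round-trip studies use the field model, so that the
recovery error of the analysis chain can be isolated (< 10⁻³ G noiseless).

## Synthetic raw data

ODMR stacks hold, per binned pixel, the product of two Lorentzian dips
(contrast 0.02, half-width parameter 8 MHz — assumed acquisition constants,
not measured quantities) centered at the transition frequencies of the
local total field; the reference channel is resonance-free unity
fluorescence; shot noise enters as independent Poisson draws on signal and
reference counts, which are then ratioed. The default budget is 10⁵
photons per (pixel, frequency) exposure — a screening-scan level; detailed
targeted scans in the recovery studies use 10⁶. An optional planar
background gradient models an imperfectly homogeneous magnetizing field.
T1 stacks follow the stretched exponential `1 − C(1 − exp(−(τ/T1)^p))`
with log-spaced dark times; under particles flagged superparamagnetic the
relaxation *rate* (rates add for independent noise sources) rises to
1/t1_particle with the profile of a PSF-blurred disk.

What the generator does *not* emulate: camera read noise and fixed-pattern
noise, drift between frequency frames, laser flicker, NV charge-state
dynamics, microwave inhomogeneity, and — deliberately — the
inhomogeneous-broadening mixture spectra of the spectral response model
(each generated pixel has one clean dip pair, so pipeline recovery is
exact). Passing round-trip tests therefore demonstrates correctness of the
analysis chain, not robustness to every instrumental artifact of real data.

## ODMR analysis pipeline

Frames are binned 2×2 (camera plus analysis convention). Each pixel's dip
is fitted with `I(ω) = 1 − CΓ²/(Γ²+(ω−ω₀)²)`; fits pinned within one
frequency step of the band edge are invalid (NaN, propagated throughout).
The field follows from the dip separation `(f₊ − f₋)/2γ` when both
transitions are swept, or from the single tracked dip with the branch of
`f₋ = |D − γB|` chosen by the nominal bias. Background removal follows the
three-step two-scale procedure: blur with a σ=50 px kernel for a coarse
background, replace the masked signal pixels with it, blur the result with
σ=25 px, subtract. Kernels are interpreted in binned pixels; on simulated
maps much smaller than the real 150 µm field of view the kernels are
scaled proportionally (the CLI scales by image size). Gaussian filtering
uses reflective boundaries, which preserve the grid sum and avoid edge
dips in the background estimate.

ΔB_NV is the max-minus-min of an offset + positive-Gaussian +
negative-Gaussian fit to a 3-pixel-wide cut through the |signal| maximum.
The cut direction is not fixed a priori (the dipolar lobes align with the
unknown in-plane field projection): both image axes are fitted and the
larger peak-to-peak retained. Gaussian centers are bounded to the window
and widths to one third of it, which prevents the degenerate
two-huge-offset-Gaussians solution on noisy cuts; degenerate fits fall
back to the raw max-minus-min with a warning. The reported error is the
SD of the pixels outside the signal mask. The fitted-curve extremum is
polished by a few Newton steps, so the metric is smooth in the fit
parameters; the residual departure from exact χ-linearity of the full
simulate-then-measure chain is at the 10⁻⁷ level (solver precision of the
ill-conditioned overlapped-Gaussian fit), while the underlying field maps
are linear to 10⁻⁹.

## Susceptibility inference

ξ is the slope of ΔB_NV versus B₀ from a weighted least-squares line with
free intercept (the slope is ξ either way for linear data; the intercept
absorbs residual background). Forward simulations evaluate ξ at the
1400 G magnetizing field; for the field response model ξ is exactly
independent of the choice of bias fields (tested to 10⁻⁶).

Bounds on χᵥ: ξ is simulated over a grid of χ (default 10⁻³–1,
log-spaced) and particle-center heights. The height grid spans
radius + implant depth (197.5 nm — particle resting on the diamond) to
section thickness + implant depth (515 nm): tissue sections are 500 nm
thick and need not contact the diamond, so centers up to about one section
thickness above the surface are physical. `chi_lo` is the smallest χ on
the ξ = ξ̄ + SD contour, `chi_hi` the largest χ on the ξ = ξ̄ − SD
contour. Grid cells are "blacked out" (excluded, NaN) when extracting
every NV's resonance would require a sweep wider than the window —
evaluated on the unblurred fine raster, since the spectrally compressed
*fitted* dips never leave the window; with the default ±50 MHz window the
masked corner starts near χ ≈ 0.075 at the lowest height and recedes with
height. Columns are interpolated in log-χ on their increasing prefix.
The measured cohort averages are combined weighting by particle count
(4 and 6 particles), giving ξ̄ = 2.78×10⁻⁴, SD = 1.18×10⁻⁴.

The easy-axis Monte Carlo draws directions uniformly on the sphere and
re-runs the forward model with everything else fixed at the reference
parameters (χᵥ = 0.053, d = 365 nm, height 207.5 nm, packing 0.7,
B₀ = 1400 G along the NV axis); the spread statistic is SD/mean of the
line-cut amplitudes. With the fixed-magnitude uniaxial model this gives
≈ 0.22 at n = 300 — the amplitude varies mainly through the pattern shape
as the moment tilts; the projection model adds the |cos| magnitude factor
on top and roughly doubles the ratio (≈ 0.57), far above the published
anisotropy spread, which is why `fixed` is the default.

## Problem sizes

Simulated images in tests and in `scripts/acceptance.py` use a 30×30
binned-pixel window (6.48 µm, oversample 6) that comfortably contains the
blurred dipolar pattern; unit tests use 20×20 (4.32 µm). The Monte Carlo
uses n = 300 draws; the acceptance ξ grid is 32 χ × 9 heights; the
end-to-end recovery study uses 20 replicates of a 4-field series at 10⁶
photons. These sizes were chosen so the whole suite and the acceptance
script each complete in minutes on a single CPU while keeping every
convergence margin (raster, dipole pitch, grid resolution) below the
tolerances being tested.

## Known limitations

* The absolute amplitude scale of the forward model is a factor ~2–4 above
  the measured cohort ξ for nominally matched parameters, and its
  amplitude-versus-height decay (~h⁻¹·⁶ over 200–500 nm, blur-limited) is
  shallower than the ~h⁻³ implied by the published susceptibility-bound
  ratio. The decisive sensor details (NV depth distribution, tissue–diamond
  gap, the exact amplitude metric of the published height sweep) are not
  in the public record; both response models implemented here bracket the
  plausible physics but do not reproduce that steep decay with a 450 nm
  PSF. Consequently the χᵥ bounds computed by this package from the same
  cohort averages come out lower than the published pair — the inversion
  machinery is validated instead by construction-and-recovery (a known χ*
  is bracketed by the inferred bounds in ≥ 90 % of noisy replicates).
* The anisotropy torque of the feasibility module is reported at the
  angle-envelope maximum (θ = φ = 45°) because the angles behind the
  published torque value are not stated; at that maximum the gating margin
  is 4 orders of magnitude rather than 5. The published margin follows from
  the published torque, which corresponds to a smaller misalignment angle.
* The field-gradient force implements ∇U with U = ½mB directly; with the
  published inputs this gives ~2×10⁻²⁹ N. The gradient's length unit in the
  published estimate is ambiguous and its printed value is not reproducible
  from the stated formula under any standard unit reading; the formula, not
  the printed number, is the contract here. Either value is ≥ 16 orders of
  magnitude below the gating force, so the feasibility conclusion is
  unaffected.
* T1 detection uses an explicit quantitative rule (rate above the
  background median by 3 robust SDs over at least one PSF disk); the
  underlying experimental criterion is qualitative, so detection *counts*
  on real data should not be compared against this rule without
  calibration.
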