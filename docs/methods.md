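# Methods

This note documents the models, estimators, numerical choices and known
limitations of the package in one place.  Units: depth in metres positive
downward, pressure in dbar, ε in W kg⁻¹, N² and Sh² in s⁻², nitrate in
µmol kg⁻¹, flux in µmol kg⁻¹ m s⁻¹ (upward positive; multiply by
ρ/1000 for mmol m⁻² s⁻¹).

## Dissipation from microstructure shear

Under isotropy the dissipation rate is ε = 7.5 ν ⟨u_z′²⟩ with ν the
kinematic viscosity.  A falling-probe shear record is cut into 2-s
segments with 50 % overlap; each segment is linearly detrended,
Hann-windowed, and its one-sided periodogram mapped to wavenumber space
through the frozen-field relation k = f/W (W = fall speed, default
0.55 m s⁻¹).  The band integral (default 2–30 cpm, clipped to the
resolved range) gives a partial shear variance; the estimate

    ε = 7.5 ν · (band variance) / F(ε)

is iterated to a fixed point (relative tolerance 1 %, ≤ 20 iterations),
where F is the fraction of Nasmyth variance inside the band at the
current ε.  The non-dimensional Nasmyth form is the standard rational
empirical fit G₂(x) = 8.05 x^{1/3} / (1 + (20.6 x)^{3.715}), x = k/k_s,
k_s = (ε/ν³)^{1/4} cpm; its total integral satisfies the isotropy
identity to ~0.1 % (verified by quadrature in the tests).  F is evaluated
from a cached log-grid cumulative integral of G₂.

Quality control: estimates are undefined when the band would resolve
< 5 % of the Nasmyth variance ("saturated"), and flagged `poor_fit` when
the band spectrum departs from the Nasmyth shape by more than 0.6 in mean
|log₁₀| misfit after a 5-bin moving average (the averaging tames the
χ²₂ periodogram scatter; measured separations: true-Nasmyth segments
≤ ~0.55, flat noise spectra ≥ ~0.70).  This makes a white-noise record
return "undefined", not a spurious small ε.

Viscosity uses ν(T) = 1.79×10⁻⁶ · exp(−0.025 T) m² s⁻¹, within a few
percent of tabulated seawater values over 0–30 °C; 1.2×10⁻⁶ m² s⁻¹ is
the fallback when no temperature accompanies a record.

Electronic-filter and finite-sensor-size response corrections of real
shear probes are out of scope; the estimator operates on the spectrum it
is given, which for the synthetic records is exactly Nasmyth-shaped.

Closed-loop behaviour (measured by `scripts/acceptance.py`): ensemble
bias −16 % to −4 % for ε between 10⁻¹⁰ and 10⁻⁸ W kg⁻¹ (low-wavenumber
variance loss from detrending/windowing of 2-s segments dominates at low
ε), with individual-estimate 95 % envelopes of a factor ~3–5.

## Diffusivity and nitrate flux

K_ρ = Γ ε / N² with Γ = 0.2, undefined where N² ≤ 0 (the constant
mixing-efficiency closure is not defensible in unstratified water).
N² = g² ρ (β dS_A − α dT)/dP with centred 10-dbar running-window
differences and α, β, ρ evaluated at the centre sample.  The flux is
F = K_ρ · ∂NO3/∂z, the gradient being the least-squares slope of the
(depth, NO3) samples within each bin (≥ 3 samples, else undefined);
in-bin regression was chosen over bin-mean differencing for robustness to
single-sample noise.

Compositing: samples are assigned to 15-m bins centred on the EUC core
depth, after discarding everything shallower than D_ML + 10 m.  ε bins
carry percentile-bootstrap CL95; K_ρ and F combine the relative errors of
their factors in quadrature.

## Equation of state

A compact self-consistent equation of state replaces a full TEOS-10
library: σ_Θ with a quadratic-in-temperature thermal expansion
(α(T) = 1.7×10⁻⁴ + 8.5×10⁻⁶ (T − 10) K⁻¹) and constant haline
contraction (β = 7.6×10⁻⁴ kg g⁻¹), referenced to σ_Θ(10 °C, 35 g kg⁻¹)
= 26.95 kg m⁻³.  α and β are the exact analytic derivatives of σ_Θ, so
the (α, β) form of N² and the density-gradient form −(g/ρ) dσ/dz agree
by construction (the tests verify < 5 % agreement against an independent
centred-difference oracle).  Accuracy against full TEOS-10 is a few
10⁻² kg m⁻³ over 0–32 °C — ample for the synthetic closed loops; for
work with real hydrography, substitute a full TEOS-10 implementation at
this module boundary.  Pressure/depth conversion is hydrostatic with
ρ₀ = 1025 kg m⁻³ (≤ 0.3 % error above 200 m).

## Detectors

**Mixed layer**: shallowest depth where σ_Θ exceeds its surface value
(shallowest valid sample, required ≤ 15 m) by 0.125 kg m⁻³, linearly
interpolated.  The same threshold detector is used for all profile
sources; mixed-layer algorithms combining threshold and gradient criteria
for coarse float profiles are deliberately not reimplemented, and surface
density inversions are flagged rather than resolved.

**20 °C isotherm** (nitracline proxy): shallowest downward crossing below
D_ML, linearly interpolated; multiple crossings take the shallowest and
set a flag (the proxy is the upper boundary of cold, nitrate-rich water).

**EUC core**: discrete maximum of eastward velocity in 20–150 m (ties:
shallowest), then a least-squares parabola over a 32-m window centred on
it; the core is the parabola's vertex and the core speed its value there.
Degenerate fits (upward-opening, vertex outside the window, < 3 samples)
fall back to the discrete maximum with a flag.  The fit runs on raw
(unregridded) velocities by default.  On 8-m-sampled Gaussian jets the
detector agrees with a dense-grid argmax oracle to < 0.3 m.

**Shear and Ri**: velocities are regridded column-wise to a 1-m grid with
the modified-Akima (makima) interpolant — C¹, overshoot-suppressing near
flat spans — the upper 20 m are masked, and u_z, v_z are running-window
regression slopes over 10 m (equal to centred differences on linear
data).  Ri = N²/Sh² elementwise, NaN where Sh² = 0; Ri < 0.25 marks shear
instability.  The *seasonal* Ri is the ratio of the N² and Sh²
climatologies, explicitly not the climatology of instantaneous ratios
(the two differ whenever the fields co-fluctuate; a constructed
counterexample is in the tests).

**Isopycnal regridding** uses 433 σ_Θ levels over 20.0–29.5 kg m⁻³ with
resolution increasing toward higher densities; density inversions are
removed by a running maximum (flagged) before makima interpolation.

## Uncertainties

SE = σ/√n with n the number of *independent* samples: the record length
divided by the decorrelation scale, defined as the 1/e crossing of the
sample autocorrelation (linearly interpolated between integer lags).
Calibrated confidence limits count one independent sample per **two**
e-folding scales: for an AR(1) process the variance of the mean is set by
the integral timescale, which approaches 2τ_e, and with a single scale
the CL95 of red-noise series covers only ~85 %.  With the factor 2,
coverage on 5-year daily AR(1) series (τ = 10 d) is 94–95 %; on 1-year
series it drops to ~91 % (1.96 vs Student-t at small effective n, plus
finite-sample ACF bias) — a known limitation for short records.  Series
that are white at the sampling cadence (scale ≤ spacing) take n = n_raw.
CL95 = mean ± 1.96 SE; differences propagate as √(SE₁² + SE₂²)
(independence assumed).  Skewed quantities (ε) use a percentile bootstrap
(default 2000 replicates, seeded) instead.

## Climatologies

**Mooring composites**: daily series fold onto the 25-entry grid
(days 1, 16, …, 361; leap days fold to 365), nearest entry within
±7.5 days circularly; entry SE uses the effective-n rule above.  The
depth-difference cycle computes the D_EUC and D_20°C cycles individually
and differences them, propagating SEs in quadrature.

**Float-cloud weighted regression**: per entry, profiles inside an
8°×3° (lon × lat) ellipse and a circular ±45-day window; IQR outlier
filter (1.5 IQR beyond the quartiles); weighted least squares of the
value on [1, Δlon, Δlat, Δlat²] (centred on the site, so the intercept is
the site prediction) with weights exp(−d²/2L²), d the great-circle
(haversine) distance and L = 200 km.  The intercept SE is the **robust
(HC1 sandwich)** covariance: with iid profile noise but weights varying
by orders of magnitude across the ellipse, the naive WLS covariance
understates the intercept error badly (76 % coverage at 2 SE vs 92–94 %
with the sandwich).  L → ∞ reduces exactly to OLS (tested to 1e-8).
Note the ±45-day boxcar window attenuates an annual harmonic by
sinc(2π·45/365) ≈ 0.904; the estimator targets the window-averaged
seasonal cycle, and recovery tests judge it against that target.

**Monthly ε composites**: calendar-month means per depth cell with
bootstrap CL95.

## Synthetic data: what it emulates, what it does not

The generators plant known truth for every estimator:

* **Sections** (default 24 stations, 35° W–2° E, 0–200 m at 1 m):
  tanh thermocline (temperature midpoint at its centre) with the 20 °C
  depth known analytically; nitrate a piecewise-linear non-increasing
  function of temperature (zero above 20 °C, +1.25 µmol kg⁻¹ per °C of
  cooling below), placing the nitracline exactly at D_20°C; a salinity
  step at the mixed-layer base so the density-threshold D_ML is sharp; a
  Gaussian-in-depth eastward jet (plus optional westward surface flow)
  sampled on the native 8-m ADCP grid with first bin at 17 m; a
  prescribed ε field enhanced between D_ML and the core.  Gaussian iid
  noise per variable (T 0.01 °C, S 0.002 g kg⁻¹, NO3 0.3 µmol kg⁻¹,
  u 0.02 m s⁻¹ — the stated section-average velocity accuracy).
  Two factory scenarios encode the seasonal extremes: `boreal_spring`
  (core 53 m at 1.0 m s⁻¹, nitracline at 75 m *below* the core, moderate
  deep-cycle ε = 3×10⁻⁸) and `boreal_summer` (core 91 m at 0.8 m s⁻¹,
  nitracline at ~57 m inside the mixing layer, enhanced ε = 10⁻⁷,
  westward surface flow).  The jet-core truth is a dense-grid argmax of
  the analytic field, not the nominal Gaussian centre.
* **Shear records**: random-phase (complex-Gaussian) Fourier synthesis
  against the Nasmyth spectrum at a prescribed ε (rejected outside
  10⁻¹¹–10⁻⁴ W kg⁻¹), Hermitian one-sided construction, default 120 s at
  512 Hz.  The ensemble-mean periodogram matches the target within 10 %
  in the integration band (tested over 50 records).
* **Moorings**: daily series = mean + annual + semiannual harmonics +
  AR(1) noise with a known e-folding timescale (analytic, hence
  testable).  Default phasing plants the core deepest around day 250 and
  the 20 °C isotherm shallowest in boreal summer, so the depth difference
  peaks mid-year (~day 210–240).
* **Float clouds**: planted seasonal harmonic + linear lon + linear and
  quadratic lat gradients + iid noise, positions uniform over the
  sampling ellipse.

Not emulated: instrument response functions, salinity/nitrate sensor
calibration drift, tropical-instability/Yanai-wave meridional shear,
internal-wave fine structure, diurnal modulation of deep-cycle
turbulence, data gaps and irregular sampling.  Passing tests therefore
demonstrate correctness of the estimators under their stated assumptions
— not robustness to every artefact of real records.

## Pipelines and problem sizes

`run_section_pipeline` chains: layer depths and EUC cores per station →
1-m shear regrid → synthesized per-station microstructure (3 profiles per
station, one record per 4-m depth cell, duration = cell/fall-speed at
256 Hz) → per-segment ε → EUC-relative 15-m composites of u, Sh², ε, N²,
NO3, K_ρ, F with CL95 → optional CSV/NetCDF/JSON outputs plus a manifest
(package and library versions, seed, config hash).  `run_mooring_pipeline`
chains: harmonic + AR(1) depth series → individual and difference
climatologies → moored-ε monthly climatology → daily jet velocities and a
pycnocline-tracking N² series → 10-day means → Sh² and N² climatologies →
seasonal Ri.  Default sizes (24 stations; 6-year moorings) keep a full
two-scenario run under ~30 s on one CPU; tests use reduced copies (5
stations, 4-year moorings) of the same configurations.

NetCDF I/O uses xarray's scipy backend (NetCDF3) with CF-style attributes
(`units`, `positive: down`); station tables are CSV; truth records and
manifests JSON.  Round trips are tested lossless.

## Design choices on genuinely open points

* Integration band 2–30 cpm and 50 % overlap are configurable defaults;
  the band's upper limit is clipped to the resolved range.
* The quadratic EUC fit uses raw velocities (regridded input is also
  accepted); fit degeneracies fall back to the discrete maximum with a
  flag rather than returning nothing.
* The Argo-style regression centres predictors on the site, making the
  intercept the site prediction.
* Percentile bootstrap (not BCa); simplest defensible default, seeded.
* n_eff floors at 2 so an SE is always defined (flagged).
* The e-folding estimator's "no crossing within half the record" guard is
  retained but unreachable for the biased (tapered) sample ACF, whose lag
  sum is −1/2 for demeaned series; the bound is asserted in tests
  instead.
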