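# equaflux

Turbulent nitrate supply to the equatorial mixed layer: from raw-style
oceanographic profiles to dissipation rates, diapycnal diffusivities,
upward diffusive nitrate fluxes, and seasonal climatologies — with a
synthetic-data layer that makes every stage verifiable against planted
ground truth.

## The problem

Productivity in the eastern equatorial Atlantic is limited by nitrate
reaching the sunlit mixed layer from below.  Three depth surfaces control
that supply: the mixed-layer base `D_ML`, the core of the eastward
Equatorial Undercurrent (EUC) `D_EUC` (depth of maximum eastward
velocity), and the nitracline, proxied by the 20 °C isotherm `D_20°C`.
Turbulence in the sheared "deep cycle" layer between `D_ML` and `D_EUC`
mixes nitrate upward — but only when the nitracline sits inside that
layer.  The package implements the full observational analysis chain used
to quantify this:

* **Dissipation rate** ε (W kg⁻¹) from microstructure shear: the
  wavenumber shear spectrum of overlapping 2-s segments is integrated over
  a limited band (default 2–30 cpm, frequency mapped to wavenumber through
  the probe fall speed) and corrected for unresolved variance by iterating
  against the universal Nasmyth spectrum, assuming isotropy
  (ε = 7.5 ν ⟨u_z′²⟩).
* **Diapycnal diffusivity** via the Osborn relation `K_ρ = Γ ε / N²`
  with mixing efficiency Γ = 0.2 and `N²` from a 10-dbar running-window
  TEOS-10-style formula `N² = g² ρ (β dS_A − α dT)/dP`.
* **Upward nitrate flux** `F_NO3 = K_ρ ∂NO3/∂z`, computed in 15-m depth
  bins relative to the EUC core after discarding the mixed layer plus a
  10-m margin, with bootstrap / propagated 95 % confidence limits.
* **EUC core detection**: discrete maximum of eastward velocity in
  20–150 m refined by a quadratic fit over a 32-m window.
* **Richardson number** `Ri = N²/Sh²` with `Sh² = u_z² + v_z²` from
  10-m running-window derivatives on a 1-m modified-Akima regrid;
  seasonal `Ri` is the ratio of the `N²` and `Sh²` climatologies.
* **Seasonal climatologies** on a 25-entry (15-day) phase grid: mooring
  composites with decorrelation-aware standard errors (effective sample
  size from the autocorrelation e-folding scale), and an Argo-style
  Gaussian-distance-weighted regression climatology
  (ellipse selection, ±45-day windows, IQR outlier filter, weights
  `exp(−d²/2L²)` with L = 200 km).

Intended users: observational physical oceanographers and marine
biogeochemists who want a tested, reusable implementation of this
profile-to-flux chain, and method developers who need a synthetic test bed
with recoverable truth.

## Worked example

```python
import equaflux

# 1) closed loop: synthesize a shear record at a known dissipation rate
#    and estimate it back
rec = equaflux.make_shear_record(1e-9, seed=7, temperature=25.0, duration=60.0)
print(equaflux.record_epsilon(rec))        # -> 9.01e-10  (true: 1e-9 W/kg)

# 2) full cruise-section pipeline on the boreal-summer scenario:
#    deep jet core, shallow nitracline inside the mixing layer
cfg = equaflux.PipelineConfig(scenario="boreal_summer", seed=7)
res = equaflux.run_section_pipeline(cfg)
print(res.stations.d_euc.mean(), res.stations.core_speed.mean())
print(res.flux_above_core())
```

Output from this exact run:

```
EUC core: 90.9 +/- 0.6 m, speed 0.80 +/- 0.02 m/s
20C isotherm (nitracline proxy): 57.2 m
  rel depth   -45 m   K_rho  3.42e-05 m2/s   dNO3/dz +5.56e-03 umol/kg/m   F_NO3 +1.90e-07 umol/kg m/s
  rel depth   -30 m   K_rho  1.83e-05 m2/s   dNO3/dz +5.32e-01 umol/kg/m   F_NO3 +9.74e-06 umol/kg m/s
  rel depth   -15 m   K_rho  3.41e-05 m2/s   dNO3/dz +1.77e-01 umol/kg/m   F_NO3 +6.05e-06 umol/kg m/s
  rel depth    +0 m   K_rho  4.23e-06 m2/s   dNO3/dz +1.78e-02 umol/kg/m   F_NO3 +7.54e-08 umol/kg m/s
mean upward nitrate flux above the core: 3.15e-06 umol/kg m/s
```

Read it as: the detector recovers the planted jet (core 91 m, 0.8 m s⁻¹);
the nitracline (57 m) lies in the turbulent layer above the core, so the
nitrate gradient and hence the upward flux peak 15–30 m above the core,
while the core itself — a `K_ρ` minimum — acts as a flux barrier.  Running
the same pipeline on the `boreal_spring` scenario (shallow 53-m core at
1.0 m s⁻¹, nitracline *below* the core) gives an above-core flux
indistinguishable from zero: the seasonal contrast that shapes equatorial
productivity.

A thin CLI mirrors the library:
`equaflux synth section --seed 1 --out d/`, `equaflux run section|mooring`,
`equaflux layers`, `equaflux euc`, `equaflux shear`, `equaflux stats`.

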