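"""Synthetic cruise sections, shear records, mooring series and float clouds.

Every generator plants a known ground truth and returns it alongside the
data, so each analysis stage has a recoverable target:

* :func:`make_section` — an equatorial section with an eastward subsurface
  jet (Gaussian in depth), a tanh thermocline whose 20 degC surface is the
  nitracline (nitrate is a monotone function of temperature), a
  salinity-step mixed-layer base, and a prescribed dissipation field
  enhanced between the mixed layer and the jet core.
* :func:`make_shear_record` — random-phase Fourier synthesis of a shear
  series whose wavenumber spectrum is the Nasmyth form at a prescribed
  epsilon (Taylor frozen-field mapping through the fall speed).
* :func:`make_mooring` — daily depth series (jet core, 20 degC isotherm)
  as mean + annual + semiannual harmonics + AR(1) noise with a known
  e-folding timescale.
* :func:`make_argo_cloud` — scattered (lon, lat, day-of-year, value)
  profiles: planted seasonal harmonic + linear/quadratic spatial gradients
  + iid noise, for the weighted-regression climatology.

All generators are deterministic for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable

import numpy as np

from . import eos
from .currents import VelocityField
from .hydrography import Profile
from .turbulence import EPS_MAX, EPS_MIN, ShearRecord, nasmyth_spectrum


def _as_func(value) -> Callable[[np.ndarray], np.ndarray]:
    """Lift a scalar to a constant function of longitude."""
    if callable(value):
        return value
    v = float(value)
    return lambda x: np.full_like(np.asarray(x, float), v)


def default_nitrate_relation(t):
    """Piecewise-linear monotone T -> NO3 map (umol/kg).

    Zero in warm water, increasing by 1.25 umol/kg per degC of cooling
    below 20 degC — a sharp nitracline co-located with the 20 degC
    isotherm.
    """
    return np.clip(1.25 * (20.0 - np.asarray(t, float)), 0.0, None)


@dataclass
class SectionScenario:
    """Configuration of a synthetic trans-basin section.

    ``euc_core_depth``, ``euc_core_speed`` and ``thermocline_depth`` may be
    scalars or callables of longitude (degE).  The default emulates a
    boreal-spring regime: shallow fast jet, thermocline (and nitracline)
    below the core.
    """

    n_stations: int = 24
    lon_west: float = -35.0
    lon_east: float = 2.0
    depth_step: float = 1.0
    depth_max: float = 200.0
    euc_core_depth: object = 53.0          # m
    euc_core_speed: object = 1.0           # m/s
    euc_width_z: float = 35.0              # Gaussian e-folding width, m
    surface_westward: float = 0.0          # m/s, westward surface flow
    thermocline_depth: object = 75.0       # m, depth of the 20 degC isotherm
    thermocline_width: float = 12.0        # tanh half-width, m
    t_surface: float = 28.0                # degC
    t_deep: float = 12.0                   # degC
    ml_depth: float = 25.0                 # m, salinity-step mixed-layer base
    sa_surface: float = 35.5               # g/kg
    sa_step: float = 0.35                  # g/kg jump at the mixed-layer base
    nitrate_relation: Callable = default_nitrate_relation
    eps_deep_cycle: float = 3e-8           # W/kg between D_ML and the core
    eps_background: float = 3e-10          # W/kg elsewhere
    noise_sd: dict = dc_field(default_factory=lambda: {
        "t": 0.01, "s": 0.002, "no3": 0.3, "u": 0.02})
    adcp_first_bin: float = 17.0           # m
    adcp_spacing: float = 8.0              # m
    seed: int = 0

    def validate(self):
        scalars = [self.euc_width_z, self.thermocline_width, self.t_surface,
                   self.t_deep, self.ml_depth, self.sa_surface, self.sa_step,
                   self.eps_deep_cycle, self.eps_background,
                   self.surface_westward]
        if not np.all(np.isfinite(scalars)):
            raise ValueError("scenario parameters must be finite")
        if self.eps_deep_cycle <= 0 or self.eps_background <= 0:
            raise ValueError("dissipation levels must be positive")
        lons = self.station_lons()
        cores = _as_func(self.euc_core_depth)(lons)
        if np.any((cores <= 20.0) | (cores >= 150.0)):
            raise ValueError("euc_core_depth must lie within (20, 150) m")
        if not np.all(np.isfinite(cores)):
            raise ValueError("euc_core_depth must be finite")
        t_chk = np.linspace(self.t_deep, self.t_surface, 50)
        rel = self.nitrate_relation(t_chk)
        if np.any(np.diff(rel) > 1e-12):
            raise ValueError("nitrate relation must be non-increasing in T")

    def station_lons(self) -> np.ndarray:
        return np.linspace(self.lon_west, self.lon_east, self.n_stations)

    def depth_grid(self) -> np.ndarray:
        return np.arange(0.0, self.depth_max + self.depth_step / 2,
                         self.depth_step)

    @classmethod
    def boreal_spring(cls, **kw) -> "SectionScenario":
        """Shallow fast core, nitracline below it, moderate mixing (April-like)."""
        return cls(**kw)

    @classmethod
    def boreal_summer(cls, **kw) -> "SectionScenario":
        """Deepened slower core, shallow nitracline in the mixing layer,
        enhanced deep-cycle dissipation, westward surface flow (July-like)."""
        defaults = dict(euc_core_depth=91.0, euc_core_speed=0.8,
                        thermocline_depth=60.0, t_surface=25.0,
                        surface_westward=0.3, eps_deep_cycle=1e-7)
        defaults.update(kw)
        return cls(**defaults)


def _temperature_field(sc: SectionScenario, z, lons):
    """Analytic T(z, lon): tanh thermocline with the 20 degC surface at its centre."""
    zt = _as_func(sc.thermocline_depth)(lons)
    zz = z[:, None]
    return sc.t_deep + (sc.t_surface - sc.t_deep) * 0.5 * (
        1.0 - np.tanh((zz - zt[None, :]) / sc.thermocline_width))


def _salinity_field(sc: SectionScenario, z, n_st):
    prof = sc.sa_surface + sc.sa_step * 0.5 * (
        1.0 + np.tanh((z - sc.ml_depth) / 2.0))
    return np.repeat(prof[:, None], n_st, axis=1)


def _velocity_field(sc: SectionScenario, z, lons):
    zc = _as_func(sc.euc_core_depth)(lons)
    sp = _as_func(sc.euc_core_speed)(lons)
    zz = z[:, None]
    jet = sp[None, :] * np.exp(-((zz - zc[None, :]) / sc.euc_width_z) ** 2)
    surface = sc.surface_westward * np.exp(-(zz / 20.0) ** 2)
    return jet - surface


def _epsilon_field(sc: SectionScenario, z, lons):
    """Prescribed dissipation: enhanced between the mixed layer and the core."""
    zc = _as_func(sc.euc_core_depth)(lons)
    zz = z[:, None]
    upper = 0.5 * (1.0 + np.tanh((zz - (sc.ml_depth + 8.0)) / 4.0))
    lower = 0.5 * (1.0 - np.tanh((zz - (zc[None, :] - 8.0)) / 6.0))
    g = upper * lower
    lg = np.log10(sc.eps_background) + (
        np.log10(sc.eps_deep_cycle) - np.log10(sc.eps_background)) * g
    return 10.0**lg


def make_section(scenario: SectionScenario):
    """Generate station profiles, an ADCP-like velocity section and the truth.

    Returns ``(profiles, velocity, truth)``: a list of
    :class:`~equaflux.hydrography.Profile` (1-m T/S/NO3 with iid noise), a
    :class:`~equaflux.currents.VelocityField` on the native ADCP grid
    (first bin 17 m, 8-m spacing), and a truth dict with per-station core
    depth/speed (dense-grid argmax of the analytic jet), 20 degC depth,
    mixed-layer depth and the dissipation field on the 1-m grid.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    lons = scenario.station_lons()
    z = scenario.depth_grid()
    n_st = lons.size

    t_true = _temperature_field(scenario, z, lons)
    s_true = _salinity_field(scenario, z, n_st)
    no3_true = scenario.nitrate_relation(t_true)

    profiles = []
    for j in range(n_st):
        t = t_true[:, j] + rng.normal(0, scenario.noise_sd["t"], z.size)
        s = s_true[:, j] + rng.normal(0, scenario.noise_sd["s"], z.size)
        no3 = no3_true[:, j] + rng.normal(0, scenario.noise_sd["no3"], z.size)
        profiles.append(Profile(depth=z, ct=t, sa=s, no3=no3,
                                lon=float(lons[j]), lat=0.0))

    z_adcp = np.arange(scenario.adcp_first_bin, scenario.depth_max + 0.5,
                       scenario.adcp_spacing)
    u_true = _velocity_field(scenario, z_adcp, lons)
    u = u_true + rng.normal(0, scenario.noise_sd["u"], u_true.shape)
    velocity = VelocityField(depth=z_adcp, axis=lons, u=u,
                             v=np.zeros_like(u), provenance="shipboard")

    # dense-grid truth for the jet core
    z_fine = np.arange(20.0, 150.0 + 1e-9, 0.02)
    u_fine = _velocity_field(scenario, z_fine, lons)
    i_max = np.argmax(u_fine, axis=0)
    # analytic 20 degC depth: invert the tanh thermocline
    if scenario.t_deep < 20.0 < scenario.t_surface:
        arg = 1.0 - 2.0 * (20.0 - scenario.t_deep) / (scenario.t_surface
                                                      - scenario.t_deep)
        z20 = (_as_func(scenario.thermocline_depth)(lons)
               + scenario.thermocline_width * np.arctanh(arg))
    else:
        z20 = np.full(n_st, np.nan)
    truth = {
        "lon": lons,
        "core_depth": z_fine[i_max],
        "core_speed": u_fine[i_max, np.arange(n_st)],
        "d_20c": z20,
        "d_ml": np.full(n_st, scenario.ml_depth),
        "depth": z,
        "epsilon": _epsilon_field(scenario, z, lons),
    }
    return profiles, velocity, truth


def make_shear_record(eps_true: float, nu: float | None = None,
                      fall_speed: float = 0.55, duration: float = 120.0,
                      sample_rate: float = 512.0, seed=None,
                      temperature: float | None = None,
                      k_required: float = 30.0) -> ShearRecord:
    """Synthesize a shear record with a Nasmyth spectrum at ``eps_true``.

    Random-phase (complex-Gaussian) Fourier synthesis against the one-sided
    target spectrum, mapped to the time domain through the frozen-field
    relation k = f / fall_speed.  The sample rate must resolve wavenumbers
    up to ``k_required`` cpm.  When ``nu`` is omitted it is derived from
    ``temperature`` (so the record is self-consistent with the estimator's
    viscosity).
    """
    if nu is None:
        nu = float(eos.kinematic_viscosity(temperature))
    if not (EPS_MIN <= eps_true <= EPS_MAX):
        raise ValueError(f"eps_true outside oceanic range "
                         f"[{EPS_MIN:g}, {EPS_MAX:g}] W/kg")
    if sample_rate / 2.0 / fall_speed < k_required:
        raise ValueError("sample rate too low to resolve the integration band")
    n = int(round(duration * sample_rate))
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    k = freqs / fall_speed
    target = np.zeros_like(freqs)
    target[1:] = nasmyth_spectrum(eps_true, nu, k[1:]) / fall_speed  # S_f(f)
    rng = np.random.default_rng(seed)
    amp = np.sqrt(target * sample_rate * n / 4.0)
    coeff = amp * (rng.standard_normal(freqs.size)
                   + 1j * rng.standard_normal(freqs.size))
    coeff[0] = 0.0
    if n % 2 == 0:
        coeff[-1] = coeff[-1].real * np.sqrt(2.0)
    shear = np.fft.irfft(coeff, n=n)
    return ShearRecord(shear=shear, sample_rate=sample_rate,
                       fall_speed=fall_speed, temperature=temperature)


def ar1_series(n: int, timescale: float, sd: float, rng,
               cadence: float = 1.0) -> np.ndarray:
    """Stationary AR(1) series with e-folding ``timescale`` and marginal ``sd``."""
    if timescale < cadence:
        raise ValueError("decorrelation timescale must be >= cadence")
    phi = np.exp(-cadence / timescale)
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    x = np.empty(n)
    x[0] = rng.normal(0, sd)
    eta = rng.normal(0, innov_sd, n - 1)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eta[i - 1]
    return x


@dataclass
class HarmonicSpec:
    """Mean + annual + semiannual harmonic of a seasonal depth series (m).

    Phases are the day-of-year of the harmonic maximum.
    """

    mean: float
    annual_amp: float = 0.0
    annual_phase: float = 0.0
    semiannual_amp: float = 0.0
    semiannual_phase: float = 0.0

    def evaluate(self, doy):
        doy = np.asarray(doy, float)
        return (self.mean
                + self.annual_amp * np.cos(2 * np.pi * (doy - self.annual_phase) / 365.0)
                + self.semiannual_amp * np.cos(4 * np.pi * (doy - self.semiannual_phase) / 365.0))


@dataclass
class MooringScenario:
    """Multi-year daily mooring series of jet-core and 20 degC depths.

    Defaults plant the observed phasing: the core is deepest in early
    autumn while the 20 degC isotherm is shallowest in boreal summer, so
    the depth difference peaks mid-year.
    """

    duration_days: float = 6 * 365.0
    cadence_days: float = 1.0
    euc: HarmonicSpec = dc_field(default_factory=lambda: HarmonicSpec(
        mean=75.0, annual_amp=20.0, annual_phase=250.0,
        semiannual_amp=4.0, semiannual_phase=40.0))
    d20: HarmonicSpec = dc_field(default_factory=lambda: HarmonicSpec(
        mean=65.0, annual_amp=15.0, annual_phase=0.0,
        semiannual_amp=3.0, semiannual_phase=120.0))
    noise_sd: float = 6.0
    decorrelation_days: float = 10.0
    seed: int = 0

    def validate(self):
        for spec in (self.euc, self.d20):
            if spec.annual_amp + spec.semiannual_amp >= spec.mean:
                raise ValueError("harmonic amplitudes must not reach the surface")
        if self.decorrelation_days < self.cadence_days:
            raise ValueError("decorrelation timescale must be >= cadence")


def make_mooring(scenario: MooringScenario):
    """Daily series of D_EUC and D_20C with AR(1) noise; truth harmonics returned.

    Returns a dict with ``time_days``, ``day_of_year``, ``d_euc``,
    ``d_20c`` and ``truth`` (the two :class:`HarmonicSpec` and the noise
    parameters).
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    t = np.arange(0.0, scenario.duration_days, scenario.cadence_days)
    doy = t % 365.0 + 1.0
    d_euc = scenario.euc.evaluate(doy)
    d_20c = scenario.d20.evaluate(doy)
    if scenario.noise_sd > 0:
        d_euc = d_euc + ar1_series(t.size, scenario.decorrelation_days,
                                   scenario.noise_sd, rng, scenario.cadence_days)
        d_20c = d_20c + ar1_series(t.size, scenario.decorrelation_days,
                                   scenario.noise_sd, rng, scenario.cadence_days)
    return {
        "time_days": t, "day_of_year": doy,
        "d_euc": d_euc, "d_20c": d_20c,
        "truth": {"euc": scenario.euc, "d20": scenario.d20,
                  "noise_sd": scenario.noise_sd,
                  "decorrelation_days": scenario.decorrelation_days},
    }


def make_argo_cloud(site=(-10.0, 0.0), n_profiles: int = 600,
                    mean: float = 50.0, annual_amp: float = 10.0,
                    annual_phase: float = 180.0, lon_slope: float = 0.0,
                    lat_slope: float = 0.0, lat_quad: float = 0.0,
                    noise_sd: float = 3.0, ellipse=(8.0, 3.0),
                    seed=None):
    """Scattered profile cloud with a planted seasonal harmonic and gradients.

    Values are ``mean + annual_amp * cos(2 pi (doy - annual_phase)/365)
    + lon_slope * dlon + lat_slope * dlat + lat_quad * dlat^2 + noise``,
    with positions uniform over the sampling ellipse and day-of-year
    uniform over the year.  Returns a dict with ``lon``, ``lat``, ``doy``,
    ``value`` and ``truth``.
    """
    if n_profiles < 50:
        raise ValueError("need at least 50 profiles")
    rng = np.random.default_rng(seed)
    r = np.sqrt(rng.uniform(0, 1, n_profiles))
    theta = rng.uniform(0, 2 * np.pi, n_profiles)
    dlon = ellipse[0] * r * np.cos(theta)
    dlat = ellipse[1] * r * np.sin(theta)
    doy = rng.uniform(1.0, 365.0, n_profiles)
    value = (mean + annual_amp * np.cos(2 * np.pi * (doy - annual_phase) / 365.0)
             + lon_slope * dlon + lat_slope * dlat + lat_quad * dlat**2
             + rng.normal(0, noise_sd, n_profiles))
    return {
        "lon": site[0] + dlon, "lat": site[1] + dlat,
        "doy": doy, "value": value,
        "truth": {"mean": mean, "annual_amp": annual_amp,
                  "annual_phase": annual_phase, "lon_slope": lon_slope,
                  "lat_slope": lat_slope, "lat_quad": lat_quad,
                  "noise_sd": noise_sd},
    }
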