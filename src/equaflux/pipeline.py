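"""End-to-end analysis drivers on synthetic scenarios.

``run_section_pipeline`` mirrors the cruise analysis: station profiles and
an ADCP section go in; layer depths, EUC cores, shear, dissipation from
synthesized microstructure, diffusivity, nitrate gradient and upward
nitrate flux come out as EUC-core-relative composites with 95 % limits.

``run_mooring_pipeline`` mirrors the moored analysis: multi-year depth
series yield individual seasonal cycles and the depth-difference cycle
with propagated SE; synthetic moored dissipation yields a monthly
climatology; daily velocity plus a stratification series yield the
seasonal Richardson-number climatology as clim(N2)/clim(Sh2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import climatology as clim
from . import eos, flux, io, synthetic, turbulence, uncertainty
from .currents import ShearField, euc_core, shear_squared, ten_day_mean, \
    VelocityField, _makima_column
from .hydrography import buoyancy_frequency_squared, layer_depths

_MONTH_EDGES = np.cumsum([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])


def month_of_doy(doy):
    """Calendar month (1-12) of a day-of-year in a 365-day year."""
    return np.searchsorted(_MONTH_EDGES, np.asarray(doy, float),
                           side="left") + 1


def _rel_bin_edges(bin_width: float, span: float = 60.0):
    half = bin_width / 2.0
    k_max = int(span // bin_width)
    return np.arange(-(k_max + 0.5) * bin_width, (k_max + 0.5) * bin_width + half,
                     bin_width)


@dataclass
class SectionResult:
    """Products of one synthetic-cruise run."""

    stations: pd.DataFrame           # per-station lon, D_ML, D_20C, D_EUC, speed
    rel_grid: np.ndarray             # 1-m EUC-relative axis for u and Sh2
    u_mean: np.ndarray
    u_cl95: np.ndarray               # half-widths
    sh2_mean: np.ndarray
    sh2_cl95: np.ndarray
    eps: turbulence.EpsilonProfile   # 15-m EUC-relative bins
    n2_mean: np.ndarray              # per 15-m bin
    no3_mean: np.ndarray             # per 15-m bin
    flux: flux.FluxProfile
    truth: dict
    manifest: dict

    def flux_above_core(self) -> float:
        """Mean upward nitrate flux in the bins above the core (umol/kg m/s)."""
        above = (self.flux.rel_depth < 0) & np.isfinite(self.flux.flux)
        if not above.any():
            return np.nan
        return float(np.mean(self.flux.flux[above]))


def run_section_pipeline(config: io.PipelineConfig, seed=None,
                         out_dir=None) -> SectionResult:
    """Run the full station-section analysis on a synthetic scenario."""
    config.validate()
    if seed is None:
        seed = config.seed
    factory = getattr(synthetic.SectionScenario, config.scenario)
    scenario = factory(seed=seed, **config.scenario_overrides)
    profiles, velocity, truth = synthetic.make_section(scenario)
    if not profiles:
        raise ValueError("empty section")
    rng = np.random.default_rng(seed + 1)

    rows = []
    for j, p in enumerate(profiles):
        ld = layer_depths(p)
        core = euc_core(velocity.depth, velocity.u[:, j])
        rows.append(dict(station=j, lon=p.lon, d_ml=ld.d_ml, d_20c=ld.d_20c,
                         d_euc=core.depth, core_speed=core.speed,
                         flags=";".join(sorted(ld.flags | core.flags))))
    stations = pd.DataFrame(rows)

    shear = shear_squared(velocity)
    grid_1m = shear.depth

    # synthesized microstructure: per-station falling-probe records in
    # cell_height cells, estimated back to epsilon segment by segment
    eps_rel, eps_val = [], []
    n2_rel, n2_val = [], []
    no3_rel, no3_val = [], []
    cells = np.arange(6.0, scenario.depth_max - 2.0, config.micro_cell_height)
    for j, p in enumerate(profiles):
        d_euc = stations.loc[j, "d_euc"]
        d_ml = stations.loc[j, "d_ml"]
        if not (np.isfinite(d_euc) and np.isfinite(d_ml)):
            continue
        eps_true_z = np.interp(cells, truth["depth"], truth["epsilon"][:, j])
        t_z = np.interp(cells, p.depth, p.ct)
        lowest = d_ml + flux.ML_MARGIN
        for _ in range(config.micro_profiles_per_station):
            for zc, et, tc in zip(cells, eps_true_z, t_z):
                if zc < lowest:
                    continue
                rec = synthetic.make_shear_record(
                    et, nu=float(eos.kinematic_viscosity(tc)),
                    fall_speed=config.fall_speed,
                    duration=config.micro_cell_height / config.fall_speed,
                    sample_rate=config.micro_sample_rate,
                    seed=int(rng.integers(2**31)), temperature=tc)
                for est in turbulence.epsilon_from_record(rec, band=config.band):
                    if np.isfinite(est.epsilon):
                        eps_rel.append(zc - d_euc)
                        eps_val.append(est.epsilon)
        n2 = buoyancy_frequency_squared(p)
        keep = np.isfinite(n2) & (p.depth >= lowest)
        n2_rel.extend(p.depth[keep] - d_euc)
        n2_val.extend(n2[keep])
        keep = np.isfinite(p.no3) & (p.depth >= lowest)
        no3_rel.extend(p.depth[keep] - d_euc)
        no3_val.extend(p.no3[keep])

    edges = _rel_bin_edges(config.bin_width)
    eps_prof = turbulence.profile_epsilon(
        np.array(eps_rel), np.array(eps_val), edges,
        seed=int(rng.integers(2**31)))

    def bin_mean(rel, val):
        rel = np.asarray(rel, float)
        val = np.asarray(val, float)
        mean = np.full(eps_prof.depth.size, np.nan)
        se = np.full(eps_prof.depth.size, np.nan)
        which = np.digitize(rel, edges) - 1
        for b in range(eps_prof.depth.size):
            v = val[which == b]
            if v.size:
                mean[b] = v.mean()
                se[b] = v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else np.nan
        return mean, se

    n2_mean, n2_se = bin_mean(n2_rel, n2_val)
    no3_mean, _ = bin_mean(no3_rel, no3_val)

    k_rho = flux.diffusivity(eps_prof.epsilon, n2_mean, config.gamma)
    with np.errstate(divide="ignore", invalid="ignore"):
        eps_rel_err = (eps_prof.cl95_hi - eps_prof.cl95_lo) / (
            2.0 * eps_prof.epsilon)
        n2_rel_err = 1.96 * n2_se / n2_mean
    k_rel_err = uncertainty.propagate_difference(eps_rel_err, n2_rel_err)

    flux_prof = flux.nitrate_flux(
        eps_prof.depth, k_rho, k_rel_err,
        np.array(no3_rel), np.array(no3_val),
        d_euc=0.0, d_ml=-np.inf, bin_width=config.bin_width, ml_margin=0.0)
    flux_prof.n_eps[:] = eps_prof.n_segments

    # EUC-relative composites of u and Sh2 (1-m axis, station-mean +/- CL95)
    rel_grid = np.arange(-60.0, 61.0)
    n_st = len(profiles)
    u_rel = np.full((rel_grid.size, n_st), np.nan)
    sh2_rel = np.full((rel_grid.size, n_st), np.nan)
    for j in range(n_st):
        d_euc = stations.loc[j, "d_euc"]
        if not np.isfinite(d_euc):
            continue
        z_abs = d_euc + rel_grid
        u_rel[:, j] = _makima_column(velocity.depth, velocity.u[:, j], z_abs)
        idx = np.round(z_abs).astype(int)
        ok = (idx >= 0) & (idx < grid_1m.size)
        sh2_rel[ok, j] = shear.sh2[idx[ok], j]

    def comp(arr):
        finite = np.isfinite(arr)
        n = finite.sum(axis=1)
        filled = np.where(finite, arr, 0.0)
        denom = np.maximum(n, 1)
        mean = filled.sum(axis=1) / denom
        var = np.where(finite, (arr - mean[:, None]) ** 2, 0.0).sum(axis=1)
        sd = np.sqrt(var / np.maximum(n - 1, 1))
        half = 1.96 * sd / np.sqrt(denom)
        half[n < 2] = np.nan
        mean[n < 2] = np.nan
        return mean, half

    u_mean, u_cl95 = comp(u_rel)
    sh2_mean, sh2_cl95 = comp(sh2_rel)

    manifest = io.run_manifest(config, seed)
    result = SectionResult(stations=stations, rel_grid=rel_grid,
                           u_mean=u_mean, u_cl95=u_cl95,
                           sh2_mean=sh2_mean, sh2_cl95=sh2_cl95,
                           eps=eps_prof, n2_mean=n2_mean, no3_mean=no3_mean,
                           flux=flux_prof, truth=truth, manifest=manifest)
    if out_dir is not None:
        _write_section(result, profiles, velocity, out_dir)
    return result


def _write_section(result: SectionResult, profiles, velocity, out_dir):
    import xarray as xr
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.stations.to_csv(out / "stations.csv", index=False)
    io.write_profiles_csv(profiles, out / "profiles.csv")
    io.write_velocity_nc(velocity, out / "velocity.nc")
    ds = xr.Dataset(
        {
            "u_mean": ("rel_depth", result.u_mean, {"units": "m s-1"}),
            "u_cl95": ("rel_depth", result.u_cl95, {"units": "m s-1"}),
            "sh2_mean": ("rel_depth", result.sh2_mean, {"units": "s-2"}),
            "sh2_cl95": ("rel_depth", result.sh2_cl95, {"units": "s-2"}),
            "epsilon": ("rel_bin", result.eps.epsilon, {"units": "W kg-1"}),
            "epsilon_cl95_lo": ("rel_bin", result.eps.cl95_lo),
            "epsilon_cl95_hi": ("rel_bin", result.eps.cl95_hi),
            "n2": ("rel_bin", result.n2_mean, {"units": "s-2"}),
            "no3": ("rel_bin", result.no3_mean, {"units": "umol kg-1"}),
            "k_rho": ("rel_bin", result.flux.k_rho, {"units": "m2 s-1"}),
            "no3_gradient": ("rel_bin", result.flux.no3_gradient,
                             {"units": "umol kg-1 m-1"}),
            "f_no3": ("rel_bin", result.flux.flux,
                      {"units": "umol kg-1 m s-1", "positive": "up"}),
            "f_no3_cl95_lo": ("rel_bin", result.flux.flux_cl95_lo),
            "f_no3_cl95_hi": ("rel_bin", result.flux.flux_cl95_hi),
        },
        coords={"rel_depth": ("rel_depth", result.rel_grid,
                              {"units": "m", "long_name":
                               "depth relative to EUC core, positive down"}),
                "rel_bin": ("rel_bin", result.flux.rel_depth, {"units": "m"})},
    )
    ds.to_netcdf(out / "composites.nc", engine="scipy")
    io.write_json(result.truth, out / "truth.json")
    io.write_json(result.manifest, out / "manifest.json")


@dataclass
class MooringResult:
    """Products of one synthetic multi-year mooring run."""

    clim_euc: clim.SeasonalClimatology
    clim_d20: clim.SeasonalClimatology
    depth_difference: clim.SeasonalClimatology
    eps_monthly: clim.SeasonalClimatology      # (12, n_eps_depth)
    eps_depths: np.ndarray
    ri: clim.SeasonalClimatology               # (25, n_ri_depth)
    ri_depths: np.ndarray
    truth: dict
    manifest: dict

    def difference_peak_doy(self) -> float:
        """Phase-grid day-of-year of the maximum depth difference."""
        i = np.nanargmax(self.depth_difference.value)
        return float(self.depth_difference.phase[i])


def _moored_epsilon_series(moor, depths, rng):
    """Daily moored dissipation: seasonal deep-cycle signal x lognormal noise.

    Enhanced dissipation mid-year in the layer above the (seasonally
    migrating) jet core, weak at depth; the planted maximum is in
    June/July.
    """
    doy = moor["day_of_year"]
    seasonal = 0.5 * (1.0 + np.cos(2 * np.pi * (doy - 182.0) / 365.0))
    eps = np.empty((len(depths), doy.size))
    for i, z in enumerate(depths):
        layer = np.exp(-((z - 45.0) / 25.0) ** 2)
        log_mean = -9.0 + 1.5 * seasonal * layer
        eps[i] = 10.0 ** (log_mean + rng.normal(0, 0.4, doy.size))
    return eps


def run_mooring_pipeline(config: io.PipelineConfig, seed=None,
                         out_dir=None) -> MooringResult:
    """Run the full moored-series analysis on a synthetic scenario."""
    config.validate()
    if seed is None:
        seed = config.seed
    scenario = synthetic.MooringScenario(
        duration_days=config.mooring_years * 365.0, seed=seed)
    moor = synthetic.make_mooring(scenario)
    rng = np.random.default_rng(seed + 1)
    doy = moor["day_of_year"]

    clim_euc = clim.mooring_seasonal_cycle(doy, moor["d_euc"])
    clim_d20 = clim.mooring_seasonal_cycle(doy, moor["d_20c"])
    diff = clim.depth_difference_cycle(clim_euc, clim_d20)

    eps_depths = np.array([30.0, 45.0, 60.0, 75.0, 90.0])
    eps_series = _moored_epsilon_series(moor, eps_depths, rng)
    eps_monthly = clim.monthly_epsilon_climatology(
        month_of_doy(doy), eps_series, seed=int(rng.integers(2**31)))

    # daily velocity profiles with the core at the (noisy) moored core depth
    z_adcp = np.arange(17.0, 201.0, 8.0)
    core = np.clip(moor["d_euc"], 25.0, 145.0)
    u = 0.9 * np.exp(-((z_adcp[:, None] - core[None, :]) / 35.0) ** 2)
    u += rng.normal(0, 0.02, u.shape)
    vel = VelocityField(depth=z_adcp, axis=moor["time_days"], u=u,
                        provenance="moored")
    shear = shear_squared(vel)
    mids, sh2_10d = ten_day_mean(moor["time_days"], shear.sh2)
    mid_doy = mids % 365.0 + 1.0

    ri_depths = np.arange(25.0, 151.0, 5.0)
    iz = np.searchsorted(shear.depth, ri_depths)
    # stratification series: pycnocline tracking the 20 degC depth + red noise
    n2_true = 1.0e-5 + 9.0e-4 * np.exp(
        -((ri_depths[:, None] - moor["d_20c"][None, :]) / 15.0) ** 2)
    n2_noisy = np.clip(
        n2_true * (1.0 + 0.15 * np.vstack([
            synthetic.ar1_series(doy.size, 10.0, 1.0, rng)
            for _ in ri_depths])), 1e-7, None)
    _, n2_10d = ten_day_mean(moor["time_days"], n2_noisy)

    def stack_cycles(values_2d):
        cycles = [clim.mooring_seasonal_cycle(mid_doy, values_2d[i],
                                              cadence_days=10.0)
                  for i in range(values_2d.shape[0])]
        phase = cycles[0].phase
        return clim.SeasonalClimatology(
            phase=phase,
            value=np.column_stack([c.value for c in cycles]),
            se=np.column_stack([c.se for c in cycles]),
            n_effective=np.column_stack([c.n_effective for c in cycles]),
            flags=set().union(*(c.flags for c in cycles)))

    sh2_clim = stack_cycles(sh2_10d[iz])
    n2_clim = stack_cycles(n2_10d)
    ri = clim.ri_climatology(n2_clim, sh2_clim)

    manifest = io.run_manifest(config, seed)
    result = MooringResult(clim_euc=clim_euc, clim_d20=clim_d20,
                           depth_difference=diff, eps_monthly=eps_monthly,
                           eps_depths=eps_depths, ri=ri, ri_depths=ri_depths,
                           truth=moor["truth"], manifest=manifest)
    if out_dir is not None:
        _write_mooring(result, out_dir)
    return result


def _write_mooring(result: MooringResult, out_dir):
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_climatology_nc(result.clim_euc, "d_euc",
                            out / "clim_d_euc.nc", units="m")
    io.write_climatology_nc(result.clim_d20, "d_20c",
                            out / "clim_d_20c.nc", units="m")
    io.write_climatology_nc(result.depth_difference, "depth_difference",
                            out / "clim_depth_difference.nc", units="m")
    io.write_climatology_nc(result.eps_monthly, "epsilon",
                            out / "clim_epsilon_monthly.nc", units="W kg-1")
    io.write_climatology_nc(result.ri, "ri", out / "clim_ri.nc")
    io.write_json(result.truth, out / "truth.json")
    io.write_json(result.manifest, out / "manifest.json")
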