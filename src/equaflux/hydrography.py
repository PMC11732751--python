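"""Profile-level hydrographic feature extraction.

Mixed-layer depth from a density threshold, 20 degC-isotherm depth (the
nitracline proxy in the equatorial Atlantic), squared Brunt-Vaisala
frequency from a running-window TEOS-10-style formula, and regridding onto
pressure or isopycnal grids.

Conventions: depth is metres positive downward, pressure is dbar; profiles
may be constructed from either axis and the other is derived hydrostatically
(:mod:`equaflux.eos`).  Undefined results are NaN, with string flags on the
container types where the cause matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import Akima1DInterpolator

from . import eos


@dataclass
class Profile:
    """A single hydrographic cast.

    Parameters
    ----------
    depth, pressure : array, optional
        Vertical axis; give one, the other is derived (m positive down / dbar).
    ct : array
        Conservative temperature, degC.
    sa : array
        Absolute salinity, g/kg.
    no3 : array, optional
        Nitrate, umol/kg.
    """

    ct: np.ndarray
    sa: np.ndarray
    depth: np.ndarray | None = None
    pressure: np.ndarray | None = None
    no3: np.ndarray | None = None
    lon: float = np.nan
    lat: float = 0.0
    time: object = None

    def __post_init__(self):
        if self.depth is None and self.pressure is None:
            raise ValueError("provide depth or pressure")
        if self.depth is None:
            self.pressure = np.asarray(self.pressure, float)
            self.depth = eos.pressure_to_depth(self.pressure)
        else:
            self.depth = np.asarray(self.depth, float)
            if self.pressure is None:
                self.pressure = eos.depth_to_pressure(self.depth)
            else:
                self.pressure = np.asarray(self.pressure, float)
        self.ct = np.asarray(self.ct, float)
        self.sa = np.asarray(self.sa, float)
        if self.no3 is not None:
            self.no3 = np.asarray(self.no3, float)
        n = self.depth.size
        for name in ("pressure", "ct", "sa"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} length mismatch")
        if self.no3 is not None and self.no3.size != n:
            raise ValueError("no3 length mismatch")
        if np.any(np.diff(self.pressure) <= 0):
            raise ValueError("pressure must be strictly increasing")

    @property
    def sigma0(self) -> np.ndarray:
        """Potential density anomaly sigma_Theta (kg m-3)."""
        return eos.sigma0(self.sa, self.ct)


@dataclass
class LayerDepths:
    """Mixed-layer and 20 degC-isotherm depths for one profile (m)."""

    d_ml: float
    d_20c: float
    flags: set[str] = field(default_factory=set)


def mixed_layer_depth_threshold(profile: Profile, delta_sigma: float = 0.125,
                                max_surface_depth: float = 15.0) -> float:
    """Depth where sigma_Theta first exceeds its surface value by ``delta_sigma``.

    The "surface value" is the shallowest valid sample, which must lie above
    ``max_surface_depth`` (else NaN).  The crossing depth is linearly
    interpolated between the bracketing samples; NaN when the threshold is
    never reached.
    """
    sig = profile.sigma0
    z = profile.depth
    ok = np.isfinite(sig)
    if ok.sum() < 2:
        return np.nan
    z, sig = z[ok], sig[ok]
    if z[0] > max_surface_depth:
        return np.nan
    target = sig[0] + delta_sigma
    above = sig >= target
    if not above.any():
        return np.nan
    j = np.argmax(above)
    if j == 0:
        return float(z[0])
    frac = (target - sig[j - 1]) / (sig[j] - sig[j - 1])
    return float(z[j - 1] + frac * (z[j] - z[j - 1]))


def isotherm_depth(profile: Profile, t_iso: float = 20.0,
                   min_depth: float | None = None,
                   count_crossings: bool = False):
    """Depth of the shallowest downward crossing of ``t_iso``.

    A downward crossing is a sample pair with T >= t_iso above and
    T < t_iso below; the depth is linearly interpolated.  ``min_depth``
    (typically the mixed-layer depth) restricts the search to crossings at
    or below it.  NaN when the temperature never crosses.  With
    ``count_crossings`` the number of crossings in range is also returned,
    so callers can flag non-monotone profiles.
    """
    t = profile.ct
    z = profile.depth
    ok = np.isfinite(t)
    if ok.sum() < 2:
        return (np.nan, 0) if count_crossings else np.nan
    z, t = z[ok], t[ok]
    upper = t[:-1] >= t_iso
    lower = t[1:] < t_iso
    cross = upper & lower
    if min_depth is not None and np.isfinite(min_depth):
        cross &= z[1:] >= min_depth
    idx = np.nonzero(cross)[0]
    if idx.size == 0:
        return (np.nan, 0) if count_crossings else np.nan
    j = idx[0]
    frac = (t[j] - t_iso) / (t[j] - t[j + 1])
    d = float(z[j] + frac * (z[j + 1] - z[j]))
    return (d, int(idx.size)) if count_crossings else d


def layer_depths(profile: Profile, delta_sigma: float = 0.125,
                 t_iso: float = 20.0) -> LayerDepths:
    """Both detectors with quality flags for one profile."""
    flags: set[str] = set()
    d_ml = mixed_layer_depth_threshold(profile, delta_sigma)
    if not np.isfinite(d_ml):
        flags.add("d_ml_undefined")
    d20, ncross = isotherm_depth(
        profile, t_iso, min_depth=d_ml if np.isfinite(d_ml) else None,
        count_crossings=True)
    if not np.isfinite(d20):
        flags.add("d_20c_undefined")
    if ncross > 1:
        flags.add("multiple_isotherm_crossings")
    if np.isfinite(d_ml) and np.isfinite(d20) and d_ml > d20:
        flags.add("ml_below_isotherm")
    return LayerDepths(d_ml=d_ml, d_20c=d20, flags=flags)


def buoyancy_frequency_squared(profile: Profile, window: float = 10.0) -> np.ndarray:
    """Squared Brunt-Vaisala frequency N2 (s-2) on the profile's pressure grid.

    N2 = g^2 rho (beta dSA - alpha dT) / dP with the differences taken over a
    centred running window of ``window`` dbar (dP in Pa); alpha, beta and rho
    evaluated at the centre sample.  Samples whose window extends past the
    profile ends are NaN.
    """
    p = profile.pressure
    ok = np.isfinite(profile.ct) & np.isfinite(profile.sa)
    if ok.sum() < 2:
        return np.full_like(p, np.nan)
    pv, tv, sv = p[ok], profile.ct[ok], profile.sa[ok]
    half = window / 2.0
    p_lo, p_hi = p - half, p + half
    t_lo = np.interp(p_lo, pv, tv, left=np.nan, right=np.nan)
    t_hi = np.interp(p_hi, pv, tv, left=np.nan, right=np.nan)
    s_lo = np.interp(p_lo, pv, sv, left=np.nan, right=np.nan)
    s_hi = np.interp(p_hi, pv, sv, left=np.nan, right=np.nan)
    t_c = np.interp(p, pv, tv)
    s_c = np.interp(p, pv, sv)
    alpha = eos.thermal_expansion(t_c)
    beta = eos.haline_contraction()
    rho = eos.rho(s_c, t_c)
    dp_pa = window * 1.0e4
    n2 = eos.G**2 * rho * (beta * (s_hi - s_lo) - alpha * (t_hi - t_lo)) / dp_pa
    n2[~np.isfinite(t_lo) | ~np.isfinite(t_hi)] = np.nan
    return n2


def regrid_pressure(profile: Profile, grid=None,
                    mask_mixed_layer: bool = False) -> Profile:
    """Linear interpolation of a profile onto a regular pressure grid.

    Default grid 0:1:200 dbar.  No extrapolation: grid points outside the
    sampled range are NaN, as are points shallower than the mixed-layer depth
    when ``mask_mixed_layer`` is set.
    """
    if grid is None:
        grid = np.arange(0.0, 201.0)
    grid = np.asarray(grid, float)

    def interp(y):
        ok = np.isfinite(y)
        if ok.sum() < 2:
            return np.full_like(grid, np.nan)
        return np.interp(grid, profile.pressure[ok], y[ok],
                         left=np.nan, right=np.nan)

    ct = interp(profile.ct)
    sa = interp(profile.sa)
    no3 = interp(profile.no3) if profile.no3 is not None else None
    if mask_mixed_layer:
        d_ml = mixed_layer_depth_threshold(profile)
        if np.isfinite(d_ml):
            p_ml = eos.depth_to_pressure(d_ml)
            shallow = grid < p_ml
            ct[shallow] = np.nan
            sa[shallow] = np.nan
            if no3 is not None:
                no3[shallow] = np.nan
    return Profile(pressure=grid, ct=ct, sa=sa, no3=no3,
                   lon=profile.lon, lat=profile.lat, time=profile.time)


def default_isopycnal_grid() -> np.ndarray:
    """433 sigma_Theta levels over 20.0-29.5 kg/m3, finer at higher density."""
    return np.concatenate([
        np.arange(20.0, 26.0, 0.05),       # 120 levels
        np.arange(26.0, 28.0, 0.02),       # 100 levels
        np.linspace(28.0, 29.5, 213),      # 213 levels
    ])


def regrid_isopycnal(profile: Profile, grid=None):
    """Interpolate CT, SA and pressure onto an isopycnal (sigma_Theta) grid.

    Uses the modified-Akima (makima) C1 piecewise-cubic interpolant, which
    suppresses overshoot near flat spans.  Density inversions are removed by
    a running maximum before interpolation and the affected levels flagged.

    Returns a dict with keys ``sigma``, ``ct``, ``sa``, ``pressure``,
    ``monotonized`` (bool: any inversion removed).
    """
    if grid is None:
        grid = default_isopycnal_grid()
    grid = np.asarray(grid, float)
    sig = profile.sigma0
    ok = np.isfinite(sig)
    sig, ct, sa, p = sig[ok], profile.ct[ok], profile.sa[ok], profile.pressure[ok]
    if sig.size < 2:
        nanv = np.full_like(grid, np.nan)
        return {"sigma": grid, "ct": nanv, "sa": nanv.copy(),
                "pressure": nanv.copy(), "monotonized": False}
    mono = np.maximum.accumulate(sig)
    touched = bool(np.any(mono != sig))
    # keep strictly increasing abscissa
    keep = np.concatenate([[True], np.diff(mono) > 0])
    mono, ct, sa, p = mono[keep], ct[keep], sa[keep], p[keep]
    out = {"sigma": grid, "monotonized": touched}
    for name, y in (("ct", ct), ("sa", sa), ("pressure", p)):
        if mono.size < 2:
            out[name] = np.full_like(grid, np.nan)
            continue
        f = Akima1DInterpolator(mono, y, method="makima", extrapolate=False)
        out[name] = f(grid)
    return out
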