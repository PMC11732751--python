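"""EUC core detection, velocity regridding, shear and Richardson number.

The Equatorial Undercurrent (EUC) core is the depth of maximum eastward
velocity between 20 and 150 m, refined by a quadratic fit in a 32-m window
around the discrete maximum.  Squared shear Sh2 = u_z^2 + v_z^2 is computed
on a 1-m grid (modified-Akima regridding, upper 20 m masked) with vertical
derivatives from a 10-m running-window regression slope.  Ri = N2 / Sh2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import Akima1DInterpolator


@dataclass
class VelocityField:
    """u, v (m/s) on a depth x (station | time) grid.

    ``axis`` holds station longitudes (degE) or times, in increasing order
    along the second dimension of ``u``/``v``.  Eastward u positive, depth
    positive down and increasing.
    """

    depth: np.ndarray
    axis: np.ndarray
    u: np.ndarray
    v: np.ndarray | None = None
    provenance: str = "shipboard"

    def __post_init__(self):
        self.depth = np.asarray(self.depth, float)
        self.axis = np.asarray(self.axis)
        self.u = np.atleast_2d(np.asarray(self.u, float))
        if self.v is None:
            self.v = np.zeros_like(self.u)
        else:
            self.v = np.atleast_2d(np.asarray(self.v, float))
        if np.any(np.diff(self.depth) <= 0):
            raise ValueError("depth must be strictly increasing")
        if self.u.shape != (self.depth.size, self.axis.size):
            raise ValueError("u must be (depth, axis)")
        if self.v.shape != self.u.shape:
            raise ValueError("v shape mismatch")
        for comp in (self.u, self.v):
            if np.nanmax(np.abs(comp), initial=0.0) >= 3.0:
                raise ValueError("velocity exceeds 3 m/s sanity bound")


@dataclass
class EucCore:
    """EUC core depth and speed from one velocity profile."""

    depth: float
    speed: float
    flags: set[str] = field(default_factory=set)
    n_fit: int = 0


def euc_core(depth, u, z_min: float = 20.0, z_max: float = 150.0,
             fit_window: float = 32.0) -> EucCore:
    """Locate the EUC core in a single u(z) profile.

    Discrete maximum of eastward velocity in [z_min, z_max] (ties take the
    shallowest), then a least-squares parabola over the ``fit_window`` m
    centred on it; the core is the parabola's vertex.  Degenerate fits
    (upward-opening, vertex outside the window, <3 samples) fall back to the
    discrete maximum with a flag.  A profile with no eastward flow in range
    returns NaN with flag ``no_euc``.
    """
    depth = np.asarray(depth, float)
    u = np.asarray(u, float)
    ok = np.isfinite(u) & (depth >= z_min) & (depth <= z_max)
    if not ok.any() or np.nanmax(u[ok]) <= 0.0:
        return EucCore(np.nan, np.nan, {"no_euc"})
    z_in, u_in = depth[ok], u[ok]
    i_max = int(np.argmax(u_in))  # first occurrence = shallowest
    z0, u0 = z_in[i_max], u_in[i_max]
    half = fit_window / 2.0
    w = np.abs(z_in - z0) <= half
    flags: set[str] = set()
    if w.sum() < 3:
        flags.add("fit_fallback")
        return EucCore(float(z0), float(u0), flags, int(w.sum()))
    c = np.polyfit(z_in[w] - z0, u_in[w], 2)
    a, b = c[0], c[1]
    if a >= 0:
        flags.add("fit_fallback")
        return EucCore(float(z0), float(u0), flags, int(w.sum()))
    dz = -b / (2.0 * a)
    if abs(dz) > half:
        flags.add("fit_fallback")
        return EucCore(float(z0), float(u0), flags, int(w.sum()))
    z_core = z0 + dz
    speed = float(np.polyval(c, dz))
    if not (z_min <= z_core <= z_max):
        flags.add("boundary")
    return EucCore(float(z_core), speed, flags, int(w.sum()))


def euc_core_at_station(field: VelocityField, station_time,
                        half_window=np.timedelta64(2, "h"), **kw) -> EucCore:
    """EUC core from the time-mean u profile within +/- ``half_window``.

    ``field.axis`` must be a time axis comparable with ``station_time``
    (datetime64 or numeric in consistent units).
    """
    t = field.axis
    sel = np.abs(t - station_time) <= half_window
    if not sel.any():
        return EucCore(np.nan, np.nan, {"no_pings"})
    with np.errstate(invalid="ignore"):
        u_mean = np.nanmean(field.u[:, sel], axis=1)
    return euc_core(field.depth, u_mean, **kw)


def _makima_column(z_src, y, z_out):
    ok = np.isfinite(y)
    if ok.sum() < 2:
        return np.full_like(z_out, np.nan)
    f = Akima1DInterpolator(z_src[ok], y[ok], method="makima", extrapolate=False)
    return f(z_out)


def _running_slope(y, spacing: float, window: float):
    """Least-squares slope of y over a centred running window.

    NaN wherever the window is incomplete (edges or any missing sample).
    For symmetric windows on linear data this equals centred differences.
    """
    n_half = int(round(window / 2.0 / spacing))
    npts = 2 * n_half + 1
    out = np.full_like(y, np.nan)
    if y.size < npts:
        return out
    zc = (np.arange(npts) - n_half) * spacing
    denom = np.sum(zc**2)
    win = np.lib.stride_tricks.sliding_window_view(y, npts)
    slopes = win @ zc / denom
    valid = np.all(np.isfinite(win), axis=1)
    slopes[~valid] = np.nan
    out[n_half:n_half + slopes.size] = slopes
    return out


@dataclass
class ShearField:
    """Vertical shear diagnostics on a 1-m depth grid."""

    depth: np.ndarray
    axis: np.ndarray
    u_z: np.ndarray
    v_z: np.ndarray
    sh2: np.ndarray


def shear_squared(field: VelocityField, grid=None, window: float = 10.0,
                  mask_upper: float = 20.0) -> ShearField:
    """Sh2 = u_z^2 + v_z^2 on a regular 1-m grid.

    Velocities are regridded column-wise with the modified-Akima
    interpolant, the upper ``mask_upper`` m are masked, and the vertical
    derivatives are running-window regression slopes over ``window`` m.
    """
    if grid is None:
        grid = np.arange(0.0, 201.0)
    grid = np.asarray(grid, float)
    spacing = float(grid[1] - grid[0])
    ncol = field.axis.size
    u_g = np.empty((grid.size, ncol))
    v_g = np.empty_like(u_g)
    for j in range(ncol):
        u_g[:, j] = _makima_column(field.depth, field.u[:, j], grid)
        v_g[:, j] = _makima_column(field.depth, field.v[:, j], grid)
    shallow = grid < mask_upper
    u_g[shallow] = np.nan
    v_g[shallow] = np.nan
    u_z = np.empty_like(u_g)
    v_z = np.empty_like(v_g)
    for j in range(ncol):
        u_z[:, j] = _running_slope(u_g[:, j], spacing, window)
        v_z[:, j] = _running_slope(v_g[:, j], spacing, window)
    return ShearField(depth=grid, axis=field.axis, u_z=u_z, v_z=v_z,
                      sh2=u_z**2 + v_z**2)


def richardson(n2, sh2, critical: float = 0.25):
    """Richardson number Ri = N2 / Sh2 with an instability mask.

    Sh2 = 0 yields NaN (not infinity); negative N2 gives Ri < 0, which is
    counted as unstable.  Returns ``(ri, unstable)`` where ``unstable`` is
    the boolean mask Ri < ``critical``.
    """
    n2 = np.asarray(n2, float)
    sh2 = np.asarray(sh2, float)
    if n2.shape != sh2.shape:
        raise ValueError("N2 and Sh2 grids must match")
    with np.errstate(divide="ignore", invalid="ignore"):
        ri = np.where(sh2 > 0, n2 / sh2, np.nan)
    unstable = np.isfinite(ri) & (ri < critical)
    return ri, unstable


def ten_day_mean(time_days, values, block: float = 10.0,
                 min_valid: float = 0.5):
    """Non-overlapping block means of a daily series (default 10-day blocks).

    ``values`` may be 1-D or (depth, time).  Blocks with fewer than
    ``min_valid`` of their potential samples valid are NaN.  Returns
    ``(block_mid_times, block_means)``.
    """
    t = np.asarray(time_days, float)
    v = np.asarray(values, float)
    one_d = v.ndim == 1
    if one_d:
        v = v[None, :]
    if v.shape[1] != t.size:
        raise ValueError("time axis length mismatch")
    t0 = t[0]
    idx = np.floor((t - t0) / block).astype(int)
    nblk = idx.max() + 1
    mids = t0 + (np.arange(nblk) + 0.5) * block
    out = np.full((v.shape[0], nblk), np.nan)
    for b in range(nblk):
        sel = idx == b
        n_pot = sel.sum()
        if n_pot == 0:
            continue
        chunk = v[:, sel]
        finite = np.isfinite(chunk)
        n_ok = finite.sum(axis=1)
        m = np.where(finite, chunk, 0.0).sum(axis=1) / np.maximum(n_ok, 1)
        m[n_ok < min_valid * n_pot] = np.nan
        m[n_ok == 0] = np.nan
        out[:, b] = m
    return mids, (out[0] if one_d else out)
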