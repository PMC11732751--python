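"""Seasonal climatologies with decorrelation-aware uncertainties.

Three estimators recur in the analysis:

* **Mooring composites** — multi-year daily series folded onto a 25-entry
  phase grid (every 15 days); SE uses the effective sample size from the
  series' autocorrelation e-folding scale.
* **Float-cloud weighted regression** — profiles within a degree-space
  ellipse and a circular +/-45-day window, IQR-filtered, then weighted
  least squares on [1, dlon, dlat, dlat^2] with Gaussian great-circle
  distance weights (200 km scale); the climatology value is the intercept
  (the prediction at the site) and its regression SE.
* **Monthly composites** — calendar-month means per depth cell with
  bootstrap confidence limits, for moored dissipation series.

A Richardson-number climatology is the ratio of the N2 and Sh2
climatologies — deliberately not the climatology of instantaneous ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from . import uncertainty

#: days in the climatological year (leap days folded onto day 365)
YEAR_DAYS = 365.0

#: Earth radius for great-circle distances, km
EARTH_RADIUS_KM = 6371.0


def phase_grid_15day() -> np.ndarray:
    """The 25-entry seasonal phase grid: days 1, 16, ..., 361."""
    return np.arange(1.0, 362.0, 15.0)


def circular_doy_distance(doy, centre):
    """Absolute day-of-year distance on the 365-day circle."""
    d = np.abs(np.asarray(doy, float) - centre)
    return np.minimum(d, YEAR_DAYS - d)


def fold_doy(doy):
    """Fold day-of-year onto [1, 365] (leap day 366 -> 365)."""
    return np.minimum(np.asarray(doy, float), YEAR_DAYS)


@dataclass
class SeasonalClimatology:
    """Phase-gridded climatology: value and SE per entry (1-D or phase x depth)."""

    phase: np.ndarray           # day-of-year (or month for monthly composites)
    value: np.ndarray
    se: np.ndarray
    n_effective: np.ndarray
    cl95_lo: np.ndarray | None = None
    cl95_hi: np.ndarray | None = None
    flags: set[str] = field(default_factory=set)


def mooring_seasonal_cycle(day_of_year, values, phase_grid=None,
                           cadence_days: float = 1.0) -> SeasonalClimatology:
    """Composite seasonal cycle of a (multi-year) daily series.

    Each sample joins the nearest phase entry on the 365-day circle
    (half-bin 7.5 days for the default grid).  The SE per entry is
    sd / sqrt(n_eff) with n_eff from the full-series decorrelation
    timescale (two e-folding scales per independent sample, see
    :data:`equaflux.uncertainty.SCALES_PER_SAMPLE`), so consecutive days do
    not masquerade as independent.
    """
    if phase_grid is None:
        phase_grid = phase_grid_15day()
    phase_grid = np.asarray(phase_grid, float)
    doy = fold_doy(day_of_year)
    v = np.asarray(values, float)
    if v.size < YEAR_DAYS / cadence_days:
        raise ValueError("need at least one year of data")
    ok = np.isfinite(v)
    scale, crossed = uncertainty.efold_decorrelation(v[ok], cadence_days)
    flags: set[str] = set() if crossed else {"acf_no_crossing"}
    if not np.isfinite(scale):
        scale = cadence_days  # constant series: treat samples as independent
        flags.add("zero_variance")
    if scale <= cadence_days:  # white at this cadence
        samples_per_indep = 1.0
    else:
        samples_per_indep = uncertainty.SCALES_PER_SAMPLE * scale / cadence_days
    half_bin = np.min(np.diff(phase_grid)) / 2.0 if phase_grid.size > 1 else 7.5

    nb = phase_grid.size
    val = np.full(nb, np.nan)
    se = np.full(nb, np.nan)
    neff = np.zeros(nb, int)
    for i, ph in enumerate(phase_grid):
        sel = ok & (circular_doy_distance(doy, ph) <= half_bin)
        n = sel.sum()
        if n == 0:
            continue
        vi = v[sel]
        val[i] = vi.mean()
        n_eff = max(2, min(n, int(np.floor(n / samples_per_indep))))
        neff[i] = n_eff
        se[i] = uncertainty.standard_error(vi, n_eff)
    return SeasonalClimatology(phase=phase_grid, value=val, se=se,
                               n_effective=neff, flags=flags)


def depth_difference_cycle(clim_a: SeasonalClimatology,
                           clim_b: SeasonalClimatology) -> SeasonalClimatology:
    """Climatology of (a - b) with SE propagated as sqrt(SE_a^2 + SE_b^2).

    The two input cycles are computed individually first (each with its own
    decorrelation-adjusted SE) and differenced afterwards.
    """
    if not np.array_equal(clim_a.phase, clim_b.phase):
        raise ValueError("phase grids must match")
    value = clim_a.value - clim_b.value
    se = uncertainty.propagate_difference(clim_a.se, clim_b.se)
    neff = np.minimum(clim_a.n_effective, clim_b.n_effective)
    return SeasonalClimatology(phase=clim_a.phase.copy(), value=value, se=se,
                               n_effective=neff,
                               flags=clim_a.flags | clim_b.flags)


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def iqr_filter(values):
    """Boolean mask of samples inside [Q1 - 1.5 IQR, Q3 + 1.5 IQR]."""
    v = np.asarray(values, float)
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    return (v >= q1 - 1.5 * iqr) & (v <= q3 + 1.5 * iqr)


def argo_climatology(lon, lat, day_of_year, values, site,
                     ellipse=(8.0, 3.0), phase_grid=None,
                     half_window: float = 45.0, scale_km: float = 200.0,
                     min_profiles: int = 10) -> SeasonalClimatology:
    """Seasonal climatology at a site from a scattered profile cloud.

    Per phase entry: select profiles inside the (lon, lat) ellipse
    (``ellipse`` = semi-axes in degrees) and within +/- ``half_window``
    days on the day-of-year circle; drop IQR outliers; then weighted least
    squares of the value on [1, dlon, dlat, dlat^2] (degrees, centred on
    the site) with weights exp(-d^2 / (2 L^2)), d the great-circle distance
    to the site and L = ``scale_km``.  The entry value is the fitted
    intercept (the site prediction) and the SE its robust (sandwich)
    regression standard error.  Entries with fewer than ``min_profiles`` profiles, or a
    rank-deficient design, are NaN and flagged.

    ``scale_km=np.inf`` reduces exactly to ordinary least squares.
    """
    if phase_grid is None:
        phase_grid = phase_grid_15day()
    phase_grid = np.asarray(phase_grid, float)
    lon = np.asarray(lon, float)
    lat = np.asarray(lat, float)
    doy = fold_doy(day_of_year)
    v = np.asarray(values, float)
    lon0, lat0 = site
    dlon = lon - lon0
    dlat = lat - lat0
    in_ellipse = (dlon / ellipse[0]) ** 2 + (dlat / ellipse[1]) ** 2 <= 1.0
    dist = haversine_km(lon, lat, lon0, lat0)
    if np.isinf(scale_km):
        w_all = np.ones_like(dist)
    else:
        w_all = np.exp(-dist**2 / (2.0 * scale_km**2))

    nb = phase_grid.size
    val = np.full(nb, np.nan)
    se = np.full(nb, np.nan)
    neff = np.zeros(nb, int)
    flags: set[str] = set()
    for i, ph in enumerate(phase_grid):
        sel = in_ellipse & (circular_doy_distance(doy, ph) <= half_window)
        sel &= np.isfinite(v)
        if sel.sum() < min_profiles:
            flags.add("entry_undersampled")
            continue
        inlier = iqr_filter(v[sel])
        idx = np.nonzero(sel)[0][inlier]
        if idx.size < min_profiles:
            flags.add("entry_undersampled")
            continue
        X = np.column_stack([np.ones(idx.size), dlon[idx], dlat[idx],
                             dlat[idx] ** 2])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            flags.add("rank_deficient")
            continue
        # sandwich covariance: with iid profile noise but strongly varying
        # distance weights the naive WLS covariance understates the
        # intercept error (effective n is (sum w)^2 / sum w^2, not n)
        fit = sm.WLS(v[idx], X, weights=w_all[idx]).fit(cov_type="HC1")
        val[i] = fit.params[0]
        se[i] = fit.bse[0]
        neff[i] = idx.size
    return SeasonalClimatology(phase=phase_grid, value=val, se=se,
                               n_effective=neff, flags=flags)


def ri_climatology(n2_clim: SeasonalClimatology,
                   sh2_clim: SeasonalClimatology) -> SeasonalClimatology:
    """Richardson-number climatology: clim(N2) / clim(Sh2), elementwise.

    This is the ratio of the two climatologies, *not* the climatology of
    instantaneous N2/Sh2 — the two differ whenever the fields fluctuate
    together.  SE combines the relative errors in quadrature; entries with
    Sh2 = 0 are NaN.
    """
    if not np.array_equal(n2_clim.phase, sh2_clim.phase):
        raise ValueError("phase grids must match")
    n2 = n2_clim.value
    sh2 = sh2_clim.value
    with np.errstate(divide="ignore", invalid="ignore"):
        ri = np.where(sh2 != 0, n2 / sh2, np.nan)
        rel = np.sqrt((n2_clim.se / n2) ** 2 + (sh2_clim.se / sh2) ** 2)
    se = np.abs(ri) * rel
    return SeasonalClimatology(phase=n2_clim.phase.copy(), value=ri, se=se,
                               n_effective=np.minimum(n2_clim.n_effective,
                                                      sh2_clim.n_effective),
                               flags=n2_clim.flags | sh2_clim.flags)


def monthly_epsilon_climatology(month, epsilon, reps: int = 1000,
                                seed=None) -> SeasonalClimatology:
    """Monthly composite of moored dissipation series with bootstrap CL95.

    ``month`` is the calendar month (1-12) per time sample; ``epsilon`` is
    1-D (time,) or 2-D (depth, time).  Returns a climatology on phase grid
    1..12 with value shape (12,) or (12, n_depth).
    """
    month = np.asarray(month, int)
    eps = np.asarray(epsilon, float)
    one_d = eps.ndim == 1
    if one_d:
        eps = eps[None, :]
    if eps.shape[1] != month.size:
        raise ValueError("time axis length mismatch")
    nd = eps.shape[0]
    val = np.full((12, nd), np.nan)
    se = np.full((12, nd), np.nan)
    lo = np.full((12, nd), np.nan)
    hi = np.full((12, nd), np.nan)
    n = np.zeros((12, nd), int)
    rng = np.random.default_rng(seed)
    for m in range(1, 13):
        sel = month == m
        for d in range(nd):
            v = eps[d, sel]
            v = v[np.isfinite(v)]
            n[m - 1, d] = v.size
            if v.size == 0:
                continue
            val[m - 1, d] = v.mean()
            if v.size >= 5:
                lo[m - 1, d], hi[m - 1, d] = uncertainty.bootstrap_mean_ci(
                    v, reps=reps, seed=rng.integers(2**31))
                se[m - 1, d] = (hi[m - 1, d] - lo[m - 1, d]) / (2 * 1.96)
    squeeze = (lambda a: a[:, 0]) if one_d else (lambda a: a)
    return SeasonalClimatology(phase=np.arange(1, 13, dtype=float),
                               value=squeeze(val), se=squeeze(se),
                               n_effective=squeeze(n),
                               cl95_lo=squeeze(lo), cl95_hi=squeeze(hi))
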