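"""Seasonal climatology estimators."""

import numpy as np
import pytest

from equaflux import climatology as cl
from equaflux.synthetic import (HarmonicSpec, MooringScenario, ar1_series,
                                make_argo_cloud, make_mooring)


def harmonic_series(amp=10.0, phase=180.0, mean=50.0, years=6):
    doy = np.arange(years * 365.0) % 365.0 + 1.0
    return doy, mean + amp * np.cos(2 * np.pi * (doy - phase) / 365.0)


class TestMooringSeasonalCycle:
    def test_pure_harmonic_recovered_to_grid_resolution(self):
        doy, v = harmonic_series()
        clim = cl.mooring_seasonal_cycle(doy, v)
        expect = 50.0 + 10.0 * np.cos(2 * np.pi * (clim.phase - 180.0) / 365.0)
        np.testing.assert_allclose(clim.value, expect, atol=0.1)

    def test_no_signal_ar1_consistent_with_se(self, rng):
        frac_ok = []
        for _ in range(25):
            v = ar1_series(6 * 365, 10.0, 5.0, rng)
            clim = cl.mooring_seasonal_cycle(np.arange(v.size) % 365.0 + 1, v)
            frac_ok.append(np.mean(np.abs(clim.value) <= 2 * clim.se))
        assert np.mean(frac_ok) >= 0.9

    def test_difference_of_cycles_equals_cycle_of_difference(self):
        doy, a = harmonic_series(amp=8.0, phase=100.0)
        _, b = harmonic_series(amp=5.0, phase=250.0)
        ca = cl.mooring_seasonal_cycle(doy, a)
        cb = cl.mooring_seasonal_cycle(doy, b)
        cd = cl.mooring_seasonal_cycle(doy, a - b)
        np.testing.assert_allclose(ca.value - cb.value, cd.value, atol=1e-9)

    def test_short_record_rejected(self):
        with pytest.raises(ValueError):
            cl.mooring_seasonal_cycle(np.arange(100.0) + 1, np.zeros(100))

    def test_circular_window_at_year_boundary(self):
        # an entry at day 1 must include late-December samples
        doy = np.arange(6 * 365.0) % 365.0 + 1.0
        v = np.where((doy >= 359) | (doy <= 8), 1.0, 0.0)
        clim = cl.mooring_seasonal_cycle(doy, v)
        assert clim.value[0] == pytest.approx(1.0)

    def test_phase_shift_symmetry(self):
        # shifting the input by 15 days shifts the climatology one entry
        doy, v = harmonic_series(phase=180.0)
        _, v2 = harmonic_series(phase=195.0)
        c1 = cl.mooring_seasonal_cycle(doy, v)
        c2 = cl.mooring_seasonal_cycle(doy, v2)
        # the 25-entry grid spans 361 days, so the rolled comparison is
        # exact except at the year seam (entry 0)
        np.testing.assert_allclose(np.roll(c1.value, 1)[1:], c2.value[1:],
                                   atol=0.1)


class TestDepthDifferenceCycle:
    def test_three_four_five_error_propagation(self):
        base = cl.SeasonalClimatology(
            phase=np.array([1.0]), value=np.array([10.0]),
            se=np.array([3.0]), n_effective=np.array([5]))
        other = cl.SeasonalClimatology(
            phase=np.array([1.0]), value=np.array([4.0]),
            se=np.array([4.0]), n_effective=np.array([7]))
        diff = cl.depth_difference_cycle(base, other)
        assert diff.value[0] == pytest.approx(6.0)
        assert diff.se[0] == pytest.approx(5.0)

    def test_identical_series_zero_value_sqrt2_se(self):
        doy, v = harmonic_series()
        c = cl.mooring_seasonal_cycle(doy, v + np.sin(doy))
        diff = cl.depth_difference_cycle(c, c)
        np.testing.assert_allclose(diff.value, 0.0, atol=1e-12)
        np.testing.assert_allclose(diff.se, np.sqrt(2) * c.se)

    def test_planted_phasing_yields_midyear_peak(self):
        moor = make_mooring(MooringScenario(noise_sd=3.0, seed=6))
        ce = cl.mooring_seasonal_cycle(moor["day_of_year"], moor["d_euc"])
        c2 = cl.mooring_seasonal_cycle(moor["day_of_year"], moor["d_20c"])
        diff = cl.depth_difference_cycle(ce, c2)
        peak = diff.phase[np.nanargmax(diff.value)]
        # truth harmonics place the maximum difference in boreal summer
        doy_fine = np.arange(1.0, 366.0)
        sc = MooringScenario()
        truth_diff = sc.euc.evaluate(doy_fine) - sc.d20.evaluate(doy_fine)
        truth_peak = doy_fine[np.argmax(truth_diff)]
        assert abs(peak - truth_peak) <= 30.0
        summer = (diff.phase >= 152) & (diff.phase <= 243)
        assert np.all(diff.value[summer] > 0)


class TestArgoClimatology:
    def test_planted_lon_slope_within_two_se(self, rng):
        import statsmodels.api as sm
        hits = 0
        n_rep = 25
        for _ in range(n_rep):
            cloud = make_argo_cloud(n_profiles=600, lon_slope=2.0,
                                    noise_sd=3.0,
                                    seed=int(rng.integers(2**31)))
            d = cl.haversine_km(cloud["lon"], cloud["lat"], -10.0, 0.0)
            w = np.exp(-d**2 / (2 * 200.0**2))
            sel = cl.circular_doy_distance(cloud["doy"], 181.0) <= 45.0
            X = np.column_stack([np.ones(sel.sum()), cloud["lon"][sel] + 10.0,
                                 cloud["lat"][sel], cloud["lat"][sel] ** 2])
            fit = sm.WLS(cloud["value"][sel], X,
                         weights=w[sel]).fit(cov_type="HC1")
            hits += abs(fit.params[1] - 2.0) <= 2 * fit.bse[1]
        assert hits / n_rep >= 0.8

    def test_infinite_scale_equals_ordinary_least_squares(self):
        import statsmodels.api as sm
        cloud = make_argo_cloud(n_profiles=400, lon_slope=1.0, lat_slope=0.5,
                                noise_sd=2.0, seed=21)
        clim_inf = cl.argo_climatology(cloud["lon"], cloud["lat"],
                                       cloud["doy"], cloud["value"],
                                       site=(-10.0, 0.0), scale_km=np.inf)
        # replicate one entry with plain OLS
        ph = clim_inf.phase[4]
        sel = cl.circular_doy_distance(cloud["doy"], ph) <= 45.0
        v = cloud["value"][sel]
        keep = cl.iqr_filter(v)
        dlon = cloud["lon"][sel][keep] + 10.0
        dlat = cloud["lat"][sel][keep]
        X = np.column_stack([np.ones(dlat.size), dlon, dlat, dlat**2])
        ols = sm.OLS(v[keep], X).fit()
        assert clim_inf.value[4] == pytest.approx(ols.params[0], rel=1e-8)

    def test_undersampled_entries_flagged_undefined(self):
        cloud = make_argo_cloud(n_profiles=60, seed=2)
        # keep only profiles from the first half-year
        sel = cloud["doy"] < 120
        clim = cl.argo_climatology(cloud["lon"][sel], cloud["lat"][sel],
                                   cloud["doy"][sel], cloud["value"][sel],
                                   site=(-10.0, 0.0))
        assert np.isnan(clim.value).any()
        assert "entry_undersampled" in clim.flags


class TestRiClimatology:
    def _clim(self, value, se=None):
        value = np.asarray(value, float)
        if se is None:
            se = 0.1 * np.abs(value)
        return cl.SeasonalClimatology(
            phase=np.arange(1.0, value.shape[0] + 1), value=value,
            se=np.asarray(se, float),
            n_effective=np.full(value.shape, 10))

    def test_constant_fields_give_constant_ratio(self):
        ri = cl.ri_climatology(self._clim([1e-4, 1e-4]),
                               self._clim([4e-4, 4e-4]))
        np.testing.assert_allclose(ri.value, 0.25)

    def test_ratio_of_climatologies_not_climatology_of_ratios(self, rng):
        # anticorrelated fluctuations: mean(N2/Sh2) != mean(N2)/mean(Sh2)
        x = rng.uniform(0.5, 1.5, 2000)
        n2 = 1e-4 * x
        sh2 = 4e-4 / x
        ratio_of_means = n2.mean() / sh2.mean()
        mean_of_ratios = (n2 / sh2).mean()
        assert abs(mean_of_ratios / ratio_of_means - 1.0) > 0.05
        ri = cl.ri_climatology(self._clim([n2.mean()]),
                               self._clim([sh2.mean()]))
        assert ri.value[0] == pytest.approx(ratio_of_means)

    def test_zero_shear_undefined(self):
        ri = cl.ri_climatology(self._clim([1e-4]), self._clim([0.0], se=[0.0]))
        assert np.isnan(ri.value[0])

    def test_phase_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cl.ri_climatology(self._clim([1.0]), self._clim([1.0, 2.0]))


class TestMonthlyEpsilonClimatology:
    def test_single_year_identity(self):
        month = np.arange(1, 13)
        eps = np.linspace(1e-9, 1e-8, 12)
        clim = cl.monthly_epsilon_climatology(month, eps, seed=0)
        np.testing.assert_allclose(clim.value, eps)

    def test_constant_series(self):
        month = np.tile(np.arange(1, 13), 3)
        clim = cl.monthly_epsilon_climatology(month, np.full(36, 5e-9), seed=0)
        np.testing.assert_allclose(clim.value, 5e-9)

    def test_planted_summer_maximum_recovered(self, rng):
        month = np.tile(np.repeat(np.arange(1, 13), 30), 4)
        seasonal = np.where(np.isin(month, [6, 7]), 1e-8, 1e-9)
        eps = seasonal * rng.lognormal(0.0, 0.3, month.size)
        clim = cl.monthly_epsilon_climatology(month, eps, seed=1)
        assert int(np.nanargmax(clim.value)) + 1 in (6, 7)
        assert clim.cl95_lo is not None
        assert np.all(clim.cl95_lo <= clim.value)

    def test_missing_month_undefined(self):
        month = np.tile(np.arange(1, 12), 3)  # December absent
        clim = cl.monthly_epsilon_climatology(month, np.full(33, 1e-9), seed=0)
        assert np.isnan(clim.value[11])
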