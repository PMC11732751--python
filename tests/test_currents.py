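"""EUC core detection, shear-squared and Richardson number."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from equaflux.currents import (VelocityField, euc_core, euc_core_at_station,
                               richardson, shear_squared, ten_day_mean)
from equaflux.synthetic import ar1_series


def adcp_depths():
    return np.arange(17.0, 201.0, 8.0)


class TestEucCore:
    def test_exact_parabola_recovered_to_machine_precision(self):
        z = adcp_depths()
        u = 1.0 - ((z - 53.0) / 40.0) ** 2
        core = euc_core(z, u)
        assert core.depth == pytest.approx(53.0, abs=1e-9)
        assert core.speed == pytest.approx(1.0, abs=1e-9)
        assert not core.flags

    @given(z0=st.floats(35.0, 120.0), umax=st.floats(0.3, 1.5),
           width=st.floats(25.0, 60.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_parabola_is_fit_exact_for_any_vertex(self, z0, umax, width):
        z = adcp_depths()
        u = umax - ((z - z0) / width) ** 2
        core = euc_core(z, u)
        assert core.depth == pytest.approx(z0, abs=1e-6)
        assert core.speed == pytest.approx(umax, abs=1e-6)

    def test_gaussian_jet_within_1m_of_dense_oracle(self):
        z = adcp_depths()
        u = 0.8 * np.exp(-((z - 91.0) / 30.0) ** 2)
        core = euc_core(z, u)
        z_fine = np.arange(20.0, 150.0, 0.001)
        oracle = z_fine[np.argmax(0.8 * np.exp(-((z_fine - 91.0) / 30.0) ** 2))]
        assert abs(core.depth - oracle) < 1.0

    def test_westward_profile_undefined(self):
        z = adcp_depths()
        core = euc_core(z, np.full_like(z, -0.5))
        assert np.isnan(core.depth) and "no_euc" in core.flags

    def test_tied_maxima_take_shallowest(self):
        z = np.arange(20.0, 160.0, 10.0)
        u = np.full_like(z, 0.5)  # flat: every sample ties
        core = euc_core(z, u)
        # fallback to discrete max (flat parabola) at the shallowest sample
        assert core.depth <= z[1]


class TestEucCoreAtStation:
    def test_single_profile_window_equals_direct_call(self):
        z = adcp_depths()
        u = (1.0 * np.exp(-((z - 60.0) / 45.0) ** 2))[:, None]
        t = np.array([np.datetime64("2019-10-05T12:00")])
        f = VelocityField(depth=z, axis=t, u=u)
        c1 = euc_core_at_station(f, np.datetime64("2019-10-05T13:00"))
        c2 = euc_core(z, u[:, 0])
        assert c1.depth == pytest.approx(c2.depth)

    def test_two_identical_profiles_average_to_same(self):
        z = adcp_depths()
        prof = 1.0 * np.exp(-((z - 60.0) / 45.0) ** 2)
        u = np.column_stack([prof, prof])
        t = np.array([np.datetime64("2019-10-05T11:00"),
                      np.datetime64("2019-10-05T12:30")])
        f = VelocityField(depth=z, axis=t, u=u)
        c = euc_core_at_station(f, np.datetime64("2019-10-05T12:00"))
        # averaging identical profiles must reproduce the single-profile core
        assert c.depth == pytest.approx(euc_core(z, prof).depth, abs=1e-12)
        assert c.depth == pytest.approx(60.0, abs=1.0)

    def test_drifting_core_matches_mean_profile_oracle(self):
        z = adcp_depths()
        cores = np.array([58.0, 60.0, 62.0, 64.0])
        u = np.column_stack([0.9 * np.exp(-((z - c) / 35.0) ** 2)
                             for c in cores])
        t = (np.datetime64("2019-10-05T11:00")
             + np.arange(4) * np.timedelta64(30, "m"))
        f = VelocityField(depth=z, axis=t, u=u)
        c = euc_core_at_station(f, np.datetime64("2019-10-05T11:45"))
        z_fine = np.arange(20.0, 150.0, 0.001)
        mean_fine = np.mean([0.9 * np.exp(-((z_fine - ci) / 35.0) ** 2)
                             for ci in cores], axis=0)
        assert abs(c.depth - z_fine[np.argmax(mean_fine)]) < 1.0

    def test_empty_window_flagged(self):
        z = adcp_depths()
        t = np.array([np.datetime64("2019-10-05T00:00")])
        f = VelocityField(depth=z, axis=t,
                          u=np.ones((z.size, 1)) * 0.5)
        c = euc_core_at_station(f, np.datetime64("2019-10-06T00:00"))
        assert np.isnan(c.depth) and "no_pings" in c.flags


class TestShearSquared:
    def test_linear_profile_gives_constant_sh2(self):
        z = adcp_depths()
        u = 0.02 * z
        f = VelocityField(depth=z, axis=np.array([0.0]), u=u[:, None] - 1.5)
        sf = shear_squared(f)
        valid = np.isfinite(sf.sh2[:, 0])
        assert np.allclose(sf.sh2[valid, 0], 4e-4, rtol=1e-6)

    def test_constant_velocity_gives_zero(self):
        z = adcp_depths()
        f = VelocityField(depth=z, axis=np.array([0.0]),
                          u=np.full((z.size, 1), 0.3),
                          v=np.full((z.size, 1), -0.2))
        sf = shear_squared(f)
        valid = np.isfinite(sf.sh2[:, 0])
        assert np.all(sf.sh2[valid, 0] < 1e-20)

    def test_offset_invariance(self):
        z = adcp_depths()
        u = 0.8 * np.exp(-((z - 80.0) / 30.0) ** 2)
        f1 = VelocityField(depth=z, axis=np.array([0.0]), u=u[:, None])
        f2 = VelocityField(depth=z, axis=np.array([0.0]), u=u[:, None] + 0.5)
        s1 = shear_squared(f1).sh2
        s2 = shear_squared(f2).sh2
        np.testing.assert_allclose(s1, s2, rtol=1e-7, equal_nan=True)

    def test_gaussian_jet_flank_maxima_near_inflection(self):
        z = np.arange(17.0, 201.0, 4.0)
        width = 30.0
        zc = 90.0
        u = 0.8 * np.exp(-((z - zc) / width) ** 2)
        f = VelocityField(depth=z, axis=np.array([0.0]), u=u[:, None])
        sf = shear_squared(f)
        sh2 = sf.sh2[:, 0]
        depth = sf.depth
        core_idx = np.nanargmin(np.where(np.abs(depth - zc) < 15, sh2, np.inf))
        assert abs(depth[core_idx] - zc) < 2.0
        # analytic |du/dz| maxima at zc +/- width / sqrt(2)
        upper = (depth > zc - 35) & (depth < zc - 5)
        flank = depth[upper][np.nanargmax(sh2[upper])]
        assert abs(flank - (zc - width / np.sqrt(2))) < 2.0

    def test_upper_20m_masked(self):
        z = adcp_depths()
        f = VelocityField(depth=z, axis=np.array([0.0]),
                          u=(0.01 * z)[:, None])
        sf = shear_squared(f)
        assert np.all(np.isnan(sf.sh2[sf.depth < 25.0, 0]))


class TestRichardson:
    def test_quarter_at_matching_fields(self):
        ri, unstable = richardson(np.array([1e-4]), np.array([4e-4]))
        assert ri[0] == pytest.approx(0.25)
        assert not unstable[0]

    def test_zero_shear_is_undefined_not_infinite(self):
        ri, _ = richardson(np.array([1e-4]), np.array([0.0]))
        assert np.isnan(ri[0])

    def test_negative_n2_counts_unstable(self):
        ri, unstable = richardson(np.array([-1e-5]), np.array([1e-4]))
        assert ri[0] < 0 and unstable[0]

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            richardson(np.zeros(3), np.zeros(4))


class TestTenDayMean:
    def test_constant_series_preserved(self):
        t = np.arange(100.0)
        mids, m = ten_day_mean(t, np.full(100, 7.0))
        assert np.allclose(m, 7.0)
        assert mids[0] == pytest.approx(5.0)

    def test_alternating_series_averages_to_zero(self):
        t = np.arange(100.0)
        _, m = ten_day_mean(t, np.where(np.arange(100) % 2 == 0, 1.0, -1.0))
        assert np.allclose(m, 0.0)

    def test_sparse_blocks_undefined(self):
        t = np.arange(20.0)
        v = np.full(20, 1.0)
        v[:8] = np.nan  # first block only 20 % valid
        _, m = ten_day_mean(t, v)
        assert np.isnan(m[0]) and m[1] == 1.0

    def test_ar1_block_mean_variance_matches_analytic(self, rng):
        tau, sd, m = 5.0, 1.0, 10
        phi = np.exp(-1.0 / tau)
        # analytic variance of the mean of m consecutive AR(1) samples
        s = sum((m - abs(k)) * phi ** abs(k) for k in range(-m + 1, m))
        var_analytic = sd**2 * s / m**2
        means = []
        for _ in range(400):
            x = ar1_series(m, tau, sd, rng)
            means.append(x.mean())
        assert abs(np.var(means) / var_analytic - 1.0) < 0.2
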