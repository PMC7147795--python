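import numpy as np
import pandas as pd
import pytest

from tcbloom import (
    BloomScenario,
    EddySpec,
    GeoGrid,
    StratificationParams,
    VortexParams,
    gen_bloom_fields,
    gen_eddy_ssh_currents,
    gen_profile,
    gen_sst_field,
    gen_vortex_wind,
    relative_vorticity,
)
from tcbloom.synthetic import (
    closest_approach_time_to_point,
    closest_approach_times,
    make_linear_track,
    rankine_speed,
)


@pytest.fixture
def track():
    # fast straight crossing of the study area (NE-ward)
    return make_linear_track((10.0, 66.0), (15.0, 71.0), "2017-12-02 00:00",
                             duration_hours=24.0)


class TestVortexParams:
    def test_invariants(self):
        with pytest.raises(ValueError):
            VortexParams(vmax=-1.0, rmax=50.0)
        with pytest.raises(ValueError):
            VortexParams(vmax=30.0, rmax=0.0)
        with pytest.raises(ValueError):
            VortexParams(vmax=30.0, rmax=50.0, decay_exponent=0.0)


class TestGenVortexWind:
    def test_zero_vmax_gives_background_everywhere(self, track, small_grid):
        params = VortexParams(vmax=0.0, rmax=50.0, background_wind=(3.0, -2.0))
        wind = gen_vortex_wind(track, params, small_grid, ["2017-12-02 12:00"])
        np.testing.assert_array_equal(wind.u, 3.0)
        np.testing.assert_array_equal(wind.v, -2.0)

    def test_peak_speed_at_rmax_on_dense_radial_sweep(self):
        # printed maximum sustained wind 42.5 m/s with rmax = 50 km
        params = VortexParams(vmax=42.5, rmax=50.0)
        r = np.arange(1.0, 300.0, 1.0)  # 1-km resolution transect
        speeds = rankine_speed(r, params)
        assert abs(speeds.max() - 42.5) <= 0.5
        assert r[np.argmax(speeds)] == 50.0

    def test_axisymmetry_speed_is_function_of_radius_only(self, track, small_grid):
        from tcbloom.geodesy import local_tangent_offsets

        params = VortexParams(vmax=30.0, rmax=40.0)
        when = "2017-12-02 12:00"
        wind = gen_vortex_wind(track, params, small_grid, [when])
        clat, clon = track.interpolate_position(when)
        lat2d, lon2d = small_grid.meshgrid()
        dx, dy = local_tangent_offsets(lat2d, lon2d, clat, clon)
        r_km = np.hypot(dx, dy) / 1000.0
        # every cell's speed equals the radial profile at its own radius, so
        # cells at equal radius and any azimuth carry identical speeds
        np.testing.assert_allclose(wind.speed[0], rankine_speed(r_km, params),
                                   atol=1e-9)

    def test_cyclonic_rotation_sign(self, track, small_grid):
        # north of the centre, cyclonic flow blows westward (u < 0)
        params = VortexParams(vmax=30.0, rmax=60.0)
        when = "2017-12-02 12:00"
        wind = gen_vortex_wind(track, params, small_grid, [when])
        clat, clon = track.interpolate_position(when)
        i_north = int(np.argmin(np.abs(small_grid.lats - (clat + 0.5))))
        j = int(np.argmin(np.abs(small_grid.lons - clon)))
        assert wind.u[0, i_north, j] < 0

    def test_time_outside_span_rejected(self, track, small_grid):
        params = VortexParams(vmax=30.0, rmax=50.0)
        with pytest.raises(ValueError, match="outside track span"):
            gen_vortex_wind(track, params, small_grid, ["2017-12-04 00:00"])

    def test_unmasked_everywhere(self, track, small_grid):
        params = VortexParams(vmax=30.0, rmax=50.0)
        wind = gen_vortex_wind(track, params, small_grid, ["2017-12-02 06:00"])
        assert np.all(np.isfinite(wind.u)) and np.all(np.isfinite(wind.v))


class TestGenEddySshCurrents:
    def test_empty_eddy_list(self, small_grid):
        ssh, cur = gen_eddy_ssh_currents([], small_grid)
        assert np.all(ssh.values == 0)
        assert np.all(cur.u == 0) and np.all(cur.v == 0)

    def test_cyclonic_eddy_minimum_and_positive_vorticity(self, small_grid):
        eddy = EddySpec(center=(12.5, 68.5), amplitude=-0.1, radius=90.0)
        ssh, cur = gen_eddy_ssh_currents([eddy], small_grid)
        i, j = np.unravel_index(np.argmin(ssh.values), ssh.values.shape)
        assert abs(small_grid.lats[i] - 12.5) <= small_grid.dlat
        assert abs(small_grid.lons[j] - 68.5) <= small_grid.dlon
        curlz = relative_vorticity(cur)
        assert curlz.values[i, j] > 0

    def test_counterclockwise_circulation(self, small_grid):
        eddy = EddySpec(center=(12.5, 68.5), amplitude=-0.1, radius=90.0)
        _, cur = gen_eddy_ssh_currents([eddy], small_grid)
        i = int(np.argmin(np.abs(small_grid.lats - 13.5)))  # north of centre
        j = int(np.argmin(np.abs(small_grid.lons - 68.5)))
        assert cur.u[i, j] < 0  # westward on the north flank = cyclonic

    def test_superposition_to_machine_precision(self, small_grid):
        e1 = EddySpec(center=(11.5, 67.5), amplitude=-0.1, radius=80.0)
        e2 = EddySpec(center=(13.5, 69.5), amplitude=-0.05, radius=60.0)
        both, _ = gen_eddy_ssh_currents([e1, e2], small_grid)
        a, _ = gen_eddy_ssh_currents([e1], small_grid)
        b, _ = gen_eddy_ssh_currents([e2], small_grid)
        np.testing.assert_allclose(both.values, a.values + b.values, atol=1e-12)

    def test_equatorial_grid_rejected(self):
        grid = GeoGrid(np.arange(-1.0, 3.01, 0.5), np.arange(60.0, 63.01, 0.5))
        with pytest.raises(ValueError, match="equator"):
            gen_eddy_ssh_currents([EddySpec((2.0, 61.0), -0.1, 50.0)], grid)


class TestGenProfile:
    def test_uniform_ts_gives_zero_n(self):
        from tcbloom import buoyancy_frequency

        # degenerate stratification is exercised directly on a flat profile
        from tcbloom import HydroProfile

        prof = HydroProfile(np.arange(50.0), np.full(50, 15.0), np.full(50, 35.0))
        assert np.all(buoyancy_frequency(prof).n == 0)

    def test_surface_values_exact(self):
        params = StratificationParams(sst=29.0, deep_t=12.0, thermocline_depth=46.2,
                                      thermocline_width=10.0, sss=36.5, deep_s=35.0)
        prof = gen_profile(params, np.arange(0.0, 200.0, 1.0))
        np.testing.assert_allclose(prof.temp[0], 29.0, rtol=1e-12)
        np.testing.assert_allclose(prof.sal[0], 36.5, rtol=1e-12)
        np.testing.assert_allclose(prof.temp[-1], 12.0, atol=1e-6)

    def test_non_monotone_depths_rejected(self):
        params = StratificationParams(sst=29.0, deep_t=12.0, thermocline_depth=46.2,
                                      thermocline_width=10.0)
        with pytest.raises(ValueError, match="increasing"):
            gen_profile(params, [0.0, 2.0, 1.0])

    def test_invariants(self):
        with pytest.raises(ValueError):
            StratificationParams(sst=12.0, deep_t=29.0, thermocline_depth=46.2,
                                 thermocline_width=10.0)
        with pytest.raises(ValueError):
            StratificationParams(sst=29.0, deep_t=12.0, thermocline_depth=-5.0,
                                 thermocline_width=10.0)


class TestGenBloomFields:
    def test_argmax_lags_closest_approach_exactly(self, track, daily_times,
                                                  small_grid):
        scenario = BloomScenario(baseline_chl=0.2, peak_chl=2.0, lag_days=4,
                                 cloud_fraction=0.0, seed=0)
        chl = gen_bloom_fields(track, scenario, small_grid, daily_times)
        ca_idx = closest_approach_times(track, small_grid, daily_times)
        argmax = np.argmax(chl.values, axis=0)
        np.testing.assert_array_equal(argmax - ca_idx, 4)

    def test_flat_scenario_constant(self, track, daily_times, small_grid):
        scenario = BloomScenario(baseline_chl=0.5, peak_chl=0.5, lag_days=4,
                                 cloud_fraction=0.2, seed=1)
        chl = gen_bloom_fields(track, scenario, small_grid, daily_times)
        vals = chl.values[np.isfinite(chl.values)]
        np.testing.assert_allclose(vals, 0.5, rtol=1e-12)

    def test_cloud_fraction_law_of_large_numbers(self, track, daily_times,
                                                 small_grid):
        scenario = BloomScenario(baseline_chl=0.2, peak_chl=2.0, lag_days=4,
                                 cloud_fraction=0.3, seed=7)
        chl = gen_bloom_fields(track, scenario, small_grid, daily_times)
        n = chl.values.size
        assert n >= 1e4
        frac = np.isnan(chl.values).sum() / n
        assert abs(frac - 0.30) <= 0.01

    def test_seeded_determinism_bit_identical(self, track, daily_times, small_grid):
        scenario = BloomScenario(baseline_chl=0.2, peak_chl=2.0, lag_days=3,
                                 cloud_fraction=0.4, seed=123)
        a = gen_bloom_fields(track, scenario, small_grid, daily_times)
        b = gen_bloom_fields(track, scenario, small_grid, daily_times)
        np.testing.assert_array_equal(a.values, b.values)

    def test_different_seeds_differ(self, track, daily_times, small_grid):
        base = dict(baseline_chl=0.2, peak_chl=2.0, lag_days=3, cloud_fraction=0.4)
        a = gen_bloom_fields(track, BloomScenario(seed=1, **base), small_grid,
                             daily_times)
        b = gen_bloom_fields(track, BloomScenario(seed=2, **base), small_grid,
                             daily_times)
        assert not np.array_equal(np.isnan(a.values), np.isnan(b.values))

    def test_invariants(self):
        with pytest.raises(ValueError):
            BloomScenario(baseline_chl=0.2, peak_chl=2.0, lag_days=4,
                          cloud_fraction=1.0)
        with pytest.raises(ValueError):
            BloomScenario(baseline_chl=2.0, peak_chl=0.2, lag_days=4)
        with pytest.raises(ValueError):
            BloomScenario(baseline_chl=0.2, peak_chl=2.0, lag_days=-1)


class TestGenSstField:
    def test_step_cooling_magnitude_and_duration(self, track, daily_times,
                                                 small_grid):
        sst = gen_sst_field(track, small_grid, daily_times, base_sst=29.0,
                            drop=2.0, duration_days=10.0)
        ca_idx = closest_approach_times(track, small_grid, daily_times)
        ii, jj = 5, 5
        series = sst.values[:, ii, jj]
        cold = np.where(series < 29.0)[0]
        assert series[cold].min() == 27.0
        assert cold.size == min(10, len(daily_times) - ca_idx[ii, jj] - 1)
        assert cold[0] == ca_idx[ii, jj] + 1


class TestClosestApproach:
    def test_point_helper_matches_grid(self, track, daily_times, small_grid):
        ca_idx = closest_approach_times(track, small_grid, daily_times)
        i = int(np.argmin(np.abs(small_grid.lats - 12.5)))
        j = int(np.argmin(np.abs(small_grid.lons - 68.5)))
        t = closest_approach_time_to_point(track, 12.5, 68.5, daily_times)
        assert pd.Timestamp(daily_times[ca_idx[i, j]]) == t

    def test_out_of_span_samples_excluded(self, track, small_grid):
        # long record: pixels must not lock onto pre-span tied distances
        times = pd.date_range("2017-11-22", periods=29, freq="D")
        ca_idx = closest_approach_times(track, small_grid, times)
        in_span = (times >= track.times[0]) & (times <= track.times[-1])
        valid_idx = np.where(in_span)[0]
        assert np.all(np.isin(ca_idx, valid_idx))
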