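"""Lagrangian advection, source contact search and iron scavenging."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ventbloom import lagrangian as lg, synthetic
from ventbloom.fields import FieldError
from ventbloom.lagrangian import (SourceMask, iron_fraction, rk4_step,
                                  seasonal_delivery_map, trace_last_contact)

COSLAT50 = math.cos(math.radians(50.0))
KM_PER_DEG = 111.19492664455873


def _edge_lon_east(center_lon, center_lat, radius_deg):
    """Longitude where the disk's great-circle radius crosses the parallel."""
    cr = math.cos(math.radians(radius_deg))
    s2 = math.sin(math.radians(center_lat)) ** 2
    c2 = math.cos(math.radians(center_lat)) ** 2
    return center_lon + math.degrees(math.acos((cr - s2) / c2))


class TestVelocityInterpolation:
    def test_grid_node_slice_time_exact(self):
        series, _ = synthetic.gen_velocity_series(kind="zonal_jet",
                                                  params={"U": 0.25}, n_times=5)
        j, i = 6, 10
        u, v = series.interp(series.lon[i], series.lat[j], series.time_h[2])
        assert u == pytest.approx(series.u[2, j, i], rel=1e-12)
        assert v == 0.0

    def test_time_midpoint_linear(self):
        series, _ = synthetic.gen_velocity_series(kind="uniform",
                                                  params={"U": 0.0}, n_times=2)
        series.u[1, :, :] = 0.2
        t_mid = 0.5 * (series.time_h[0] + series.time_h[1])
        u, _ = series.interp(30.0, -50.0, t_mid)
        assert u == pytest.approx(0.1, rel=1e-12)

    def test_all_neighbours_missing_is_undefined(self):
        series, _ = synthetic.gen_velocity_series(kind="uniform", n_times=2)
        series.u[:, 3:5, 3:5] = np.nan
        series.v[:, 3:5, 3:5] = np.nan
        lon = series.lon[3] + 0.5
        lat = series.lat[3] + 0.5
        u, v = series.interp(lon, lat, series.time_h[0])
        assert np.isnan(u) and np.isnan(v)

    def test_partial_missing_renormalised(self):
        series, _ = synthetic.gen_velocity_series(kind="uniform",
                                                  params={"U": 0.1}, n_times=2)
        series.u[:, 3, 3] = np.nan
        series.v[:, 3, 3] = np.nan
        u, v = series.interp(series.lon[3] + 0.5, series.lat[3] + 0.5,
                             series.time_h[0])
        assert u == pytest.approx(0.1, rel=1e-12)   # remaining corners agree

    def test_time_outside_span_rejected(self):
        series, _ = synthetic.gen_velocity_series(kind="uniform", n_times=3)
        with pytest.raises(FieldError, match="span"):
            series.time_slab(series.time_h[-1] + 100.0)


class TestRK4:
    def test_zero_field_fixed_point(self):
        series, _ = synthetic.gen_velocity_series(kind="uniform",
                                                  params={"U": 0.0, "V": 0.0},
                                                  n_times=2)
        lon, lat, ok = rk4_step(series, 30.0, -50.0, series.time_h[0], 6.0)
        assert ok and (lon, lat) == (30.0, -50.0)

    def test_one_period_orbit_return(self):
        fld = synthetic.AnalyticSolidBodyField(30.0, -50.0, period_days=30.0)
        r = 1.0                                     # scaled-plane degrees
        lon0 = 30.0 + r / COSLAT50
        lon, lat, t = lon0, -50.0, 0.0
        for _ in range(120):
            lon, lat, ok = rk4_step(fld, lon, lat, t, 6.0)
            t += 6.0
        err = math.hypot((lon - lon0) * COSLAT50, lat + 50.0)
        assert err < 1e-3 * r

    def test_dt_halving_fourth_order(self):
        fld = synthetic.AnalyticSolidBodyField(30.0, -50.0, period_days=30.0)
        errs = []
        for dt, nsteps in ((6.0, 120), (3.0, 240)):
            lon0 = 30.0 + 1.0 / COSLAT50
            lon, lat, t = lon0, -50.0, 0.0
            for _ in range(nsteps):
                lon, lat, ok = rk4_step(fld, lon, lat, t, dt)
                t += dt
            errs.append(math.hypot((lon - lon0) * COSLAT50, lat + 50.0))
        assert 12.0 <= errs[0] / errs[1] <= 20.0

    def test_radius_drift_over_ten_periods(self):
        fld = synthetic.AnalyticSolidBodyField(30.0, -50.0, period_days=30.0)
        lon, lat, t = 30.0 + 1.0 / COSLAT50, -50.0, 0.0
        for _ in range(1200):
            lon, lat, ok = rk4_step(fld, lon, lat, t, 6.0)
            t += 6.0
        r = math.hypot((lon - 30.0) * COSLAT50, lat + 50.0)
        assert abs(r - 1.0) < 0.005

    def test_beaching_on_missing_velocity(self):
        series, _ = synthetic.gen_velocity_series(kind="uniform",
                                                  params={"U": 0.5}, n_times=2)
        series.u[:, :, 10:] = np.nan
        series.v[:, :, 10:] = np.nan
        lon0 = series.lon[9] + 0.9
        lon, lat, ok = rk4_step(series, lon0, -50.0, series.time_h[0], 6.0)
        assert not ok and lon == lon0


class TestIronFraction:
    @pytest.mark.parametrize("age,efold,expected", [
        (0.0, 90.0, 1.0),
        (90.0, 90.0, math.exp(-1)),
        (90.0 * math.log(10), 90.0, 0.1),
    ])
    def test_closed_form(self, age, efold, expected):
        assert iron_fraction(age, efold) == pytest.approx(expected, abs=1e-12)

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            iron_fraction(-1.0, 90.0)

    @given(st.floats(0.0, 300.0), st.floats(10.0, 400.0))
    @settings(max_examples=50, deadline=None)
    def test_strictly_decreasing_in_age(self, age, efold):
        assert iron_fraction(age + 1.0, efold) < iron_fraction(age, efold)


class TestContactSearch:
    def _uniform_series(self, U=0.1, n_times=160):
        series, _ = synthetic.gen_velocity_series(
            kind="uniform", params={"U": U}, lon=(18.0, 48.0, 1.0),
            lat=(-56.0, -44.0, 1.0), n_times=n_times, dt_hours=24.0)
        return series

    def test_seed_inside_disk_age_zero(self):
        series = self._uniform_series()
        mask = SourceMask(label="d", kind="disk_set", disks=((30.0, -50.0, 1.0),))
        r = trace_last_contact(series, 30.2, -50.1, series.time_h[-1], [mask])
        assert r.age_days == 0.0 and r.iron_frac == 1.0
        assert r.source_label == "d"

    def test_downstream_seed_age_equals_distance_over_speed(self):
        U = 0.1
        series = self._uniform_series(U=U)
        mask = SourceMask(label="d", kind="disk_set", disks=((25.0, -50.0, 1.0),))
        edge = _edge_lon_east(25.0, -50.0, 1.0)
        dist_m = 864.0e3                            # 100 days at 0.1 m/s
        seed_lon = edge + dist_m / (KM_PER_DEG * 1e3 * COSLAT50)
        r = trace_last_contact(series, seed_lon, -50.0, series.time_h[-1],
                               [mask], lookback_days=150.0, dt_h=6.0)
        assert r.has_contact
        assert r.age_days == pytest.approx(100.0, abs=0.25)

    def test_upstream_seed_no_contact(self):
        series = self._uniform_series()
        mask = SourceMask(label="d", kind="disk_set", disks=((40.0, -50.0, 1.0),))
        r = trace_last_contact(series, 30.0, -50.0, series.time_h[-1], [mask],
                               lookback_days=100.0)
        assert not r.has_contact and r.iron_frac is None

    def test_backward_then_forward_consistency(self):
        series = self._uniform_series(U=0.12)
        mask = SourceMask(label="d", kind="disk_set", disks=((25.0, -50.0, 1.0),))
        seed_lon, seed_lat = 32.0, -50.0
        r = trace_last_contact(series, seed_lon, seed_lat, series.time_h[-1],
                               [mask], keep_path=True)
        assert r.has_contact
        t, lon, lat = r.path[-1][0], r.path[-1][1], r.path[-1][2]
        while t < series.time_h[-1] - 1e-9:
            lon, lat, ok = lg.rk4_step(series, lon, lat, t, 6.0)
            t += 6.0
        path_len = abs(seed_lon - r.path[-1][1])
        assert abs(lon - seed_lon) < 0.01 * path_len

    def test_shallow_bathymetry_mask(self):
        bathy = synthetic.gen_bathymetry()
        mask = SourceMask(label="shelf", kind="shallow_bathymetry", bathy=bathy,
                          max_depth=500.0)
        assert mask.contains(8.0, -50.0)            # western shelf
        assert not mask.contains(30.0, -50.0)       # ridge crest is deeper


class TestDeliveryMap:
    def _setup(self, U=0.1, efold=20.0):
        series, _ = synthetic.gen_velocity_series(
            kind="uniform", params={"U": U}, lon=(18.0, 48.0, 1.0),
            lat=(-56.0, -44.0, 1.0), n_times=70, dt_hours=24.0)
        mask = SourceMask(label="d", kind="disk_set", disks=((25.0, -50.0, 1.0),))
        return series, mask

    def test_two_identical_seasons_equal_single(self):
        series, mask = self._setup()
        lons = np.arange(26.0, 30.0, 1.0)
        lats = np.array([-50.0])
        one = seasonal_delivery_map([series], lons, lats, [mask],
                                    lookback_days=40.0, efold_days=20.0)
        two = seasonal_delivery_map([series, series], lons, lats, [mask],
                                    lookback_days=40.0, efold_days=20.0)
        np.testing.assert_allclose(one["delivery"].values,
                                   two["delivery"].values, equal_nan=True)

    def test_no_masks_all_missing(self):
        series, _ = self._setup()
        ds = seasonal_delivery_map([series], np.array([30.0]),
                                   np.array([-50.0]), [],
                                   lookback_days=10.0)
        assert np.isnan(ds["delivery"].values).all()

    def test_empty_season_list_rejected(self):
        with pytest.raises(ValueError):
            seasonal_delivery_map([], np.array([30.0]), np.array([-50.0]), [])

    def test_delivery_decays_downstream_10pct_contour_position(self):
        U, efold = 0.1, 20.0
        series, mask = self._setup(U, efold)
        edge = _edge_lon_east(25.0, -50.0, 1.0)
        res = 0.25
        lons = np.arange(edge + 0.2, edge + 9.0, res)
        lats = np.array([-50.0])
        ds = seasonal_delivery_map([series], lons, lats, [mask],
                                   seed_every_days=1000.0,    # single seed time
                                   lookback_days=60.0, dt_h=6.0,
                                   efold_days=efold)
        dlv = ds["delivery"].values[0]
        assert np.all(np.diff(dlv[np.isfinite(dlv)]) <= 1e-9)  # monotone decay
        # 10% contour at U tau ln10 from the source edge
        expected_m = U * efold * 86400.0 * math.log(10.0)
        expected_lon = edge + expected_m / (KM_PER_DEG * 1e3 * COSLAT50)
        k = np.nanargmin(np.abs(dlv - 10.0))
        assert abs(lons[k] - expected_lon) <= res + 1e-9
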