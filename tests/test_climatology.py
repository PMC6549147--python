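"""Density climatology: vertical binning, optimal interpolation, sections,
dynamic-height coordinate and alongstream differencing."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from ventbloom import climatology as clim, synthetic
from ventbloom.climatology import (HydroProfile, alongstream_delta_sigma,
                                   bin_profiles_vertical, extract_section,
                                   optimal_interpolation, standard_levels,
                                   to_dh_coordinate)


def _hydro(pres, temp, psal, lat=-50.0, lon=30.0, qc=1, pid="P0"):
    return HydroProfile(profile_id=pid, source="ship", qc_flag=qc,
                        time=pd.Timestamp("2010-06-01"), lat=lat, lon=lon,
                        pres=np.asarray(pres, float),
                        temp=np.asarray(temp, float),
                        psal=np.asarray(psal, float))


class TestVerticalBinning:
    def test_samples_on_levels_identity(self):
        levels = standard_levels()
        p = _hydro(levels, np.linspace(8, 2, levels.size),
                   np.full(levels.size, 34.3))
        lons, lats, sigma = bin_profiles_vertical([p], levels)
        from ventbloom.profiles import potential_density
        expected = potential_density(p.temp, p.psal, levels)
        np.testing.assert_allclose(sigma[0], expected, atol=1e-12)

    def test_no_extrapolation_below_sampled_range(self):
        levels = standard_levels()
        p = _hydro([0.0, 500.0, 1000.0], [8.0, 5.0, 3.0], [34.0, 34.3, 34.5])
        _, _, sigma = bin_profiles_vertical([p], levels)
        deep = levels > 1000.0
        assert np.isnan(sigma[0][deep]).all()
        assert np.isfinite(sigma[0][~deep]).all()

    def test_qc_and_short_profiles_dropped(self):
        levels = standard_levels()
        good = _hydro([0.0, 500.0], [8.0, 5.0], [34.0, 34.3])
        bad_qc = _hydro([0.0, 500.0], [8.0, 5.0], [34.0, 34.3], qc=4, pid="P1")
        short = _hydro([0.0, 10.0], [8.0, 8.0], [34.0, 34.0], pid="P2")
        lons, _, sigma = bin_profiles_vertical([good, bad_qc, short], levels)
        assert sigma.shape[0] == 1

    def test_linear_T_interpolation_matches_eos_within_curvature(self):
        levels = standard_levels()
        pres = np.arange(0.0, 2001.0, 100.0)       # coarser than levels
        temp = 10.0 - pres / 250.0
        p = _hydro(pres, temp, np.full(pres.size, 34.3))
        _, _, sigma = bin_profiles_vertical([p], levels)
        from ventbloom.profiles import potential_density
        direct = potential_density(10.0 - levels / 250.0,
                                   np.full(levels.size, 34.3), levels)
        np.testing.assert_allclose(sigma[0], direct, atol=1e-3)


class TestOptimalInterpolation:
    def test_constant_samples_give_constant_grid(self):
        levels = np.array([0.0, 25.0])
        n = 30
        rng = np.random.default_rng(0)
        lons = rng.uniform(25, 35, n)
        lats = rng.uniform(-52, -48, n)
        sigma = np.full((n, 2), 27.1)
        ds = optimal_interpolation(lons, lats, sigma, np.arange(26.0, 34.1, 0.5),
                                   np.arange(-51.0, -48.9, 0.5), levels)
        vals = ds["sigma"].values
        np.testing.assert_allclose(vals[np.isfinite(vals)], 27.1, rtol=1e-12)

    def test_single_sample_near_and_far(self):
        levels = np.array([0.0])
        ds = optimal_interpolation([30.0], [-50.0], [[27.0]],
                                   np.arange(10.0, 50.1, 0.5),
                                   np.arange(-51.0, -48.9, 0.5), levels,
                                   scale_km=200.0, n_eff_floor=0.2)
        near = ds["sigma"].isel(pressure=0).sel(lat=-50.0, lon=30.0,
                                                method="nearest")
        far = ds["sigma"].isel(pressure=0).sel(lat=-50.0, lon=10.0,
                                               method="nearest")
        assert float(near) == pytest.approx(27.0)
        assert np.isnan(float(far))

    def test_dense_linear_field_error_below_1pct_of_range(self):
        levels = np.array([0.0])
        rng = np.random.default_rng(3)
        n = 4000
        lons = rng.uniform(0, 60, n)
        lats = rng.uniform(-60, -40, n)
        field = 26.0 + 0.02 * (lons - 30.0)          # 1.2 kg/m3 across domain
        ds = optimal_interpolation(lons, lats, field[:, None],
                                   np.arange(25.0, 35.1, 0.5),
                                   np.arange(-51.0, -48.9, 0.5), levels,
                                   scale_km=550.0)
        glon = ds["lon"].values
        expected = 26.0 + 0.02 * (glon - 30.0)
        err = np.abs(ds["sigma"].values[0] - expected[None, :])
        assert np.nanmax(err) < 0.01 * 1.2

    def test_stable_stratification_enforced(self):
        levels = np.array([0.0, 25.0, 50.0])
        sigma = np.array([[27.2, 27.0, 27.4]])      # inverted pair
        ds = optimal_interpolation([30.0], [-50.0], sigma,
                                   np.array([30.0]), np.array([-50.0]), levels)
        col = ds["sigma"].values[:, 0, 0]
        assert np.all(np.diff(col) >= 0)
        assert ds.attrs["n_nodes_convectively_sorted"] == 1


class TestSections:
    def _clim(self):
        levels = np.array([0.0, 25.0])
        lons = np.arange(20.0, 40.1, 0.5)
        lats = np.arange(-55.0, -44.9, 0.5)
        glat, glon = np.meshgrid(lats, lons, indexing="ij")
        field = 26.0 + 0.05 * (glon - 30.0) + 0.02 * (glat + 50.0)
        sigma = np.broadcast_to(field, (2,) + field.shape).copy()
        return xr.Dataset(
            {"sigma": (("pressure", "lat", "lon"), sigma),
             "n_eff": (("lat", "lon"), np.ones_like(field))},
            coords={"pressure": levels, "lat": lats, "lon": lons})

    def test_on_grid_column_exact(self):
        ds = self._clim()
        sec = extract_section(ds, 30.0)
        np.testing.assert_allclose(sec.values,
                                   ds["sigma"].sel(lon=30.0).sel(
                                       lat=slice(-55, -47)).values)

    def test_midway_is_column_mean(self):
        ds = self._clim()
        sec = extract_section(ds, 30.25)
        a = ds["sigma"].sel(lon=30.0).sel(lat=slice(-55, -47)).values
        b = ds["sigma"].sel(lon=30.5).sel(lat=slice(-55, -47)).values
        np.testing.assert_allclose(sec.values, 0.5 * (a + b), rtol=1e-12)

    def test_outside_domain_rejected(self):
        with pytest.raises(ValueError, match="longitude"):
            extract_section(self._clim(), 90.0)


class TestDhCoordinate:
    def test_affine_dh_is_relabeling(self):
        ds = TestSections()._clim()
        sec = extract_section(ds, 30.0)
        lat = sec["lat"].values
        dh = 1.0 + 0.08 * (lat + 50.0)               # affine in latitude
        out = to_dh_coordinate(sec, dh, dh_axis=dh)
        np.testing.assert_allclose(out.values, sec.values, atol=1e-9)

    def test_identical_sections_zero_difference(self):
        ds = TestSections()._clim()
        sec = extract_section(ds, 30.0)
        lat = sec["lat"].values
        dh = 1.0 + 0.08 * (lat + 50.0)
        a = to_dh_coordinate(sec, dh)
        b = to_dh_coordinate(sec, dh)
        res = alongstream_delta_sigma(a, b, lat, dh)
        assert float(np.nanmax(np.abs(res.delta_sigma_dh.values))) < 1e-12

    def test_swapping_sections_negates_exactly(self):
        ds = TestSections()._clim()
        w = extract_section(ds, 28.0)
        e = extract_section(ds, 38.0)
        lat = w["lat"].values
        dh = 1.0 + 0.08 * (lat + 50.0)
        ew = alongstream_delta_sigma(to_dh_coordinate(e, dh),
                                     to_dh_coordinate(w, dh), lat, dh)
        we = alongstream_delta_sigma(to_dh_coordinate(w, dh),
                                     to_dh_coordinate(e, dh), lat, dh)
        np.testing.assert_allclose(ew.delta_sigma_dh.values,
                                   -we.delta_sigma_dh.values, atol=1e-12)

    def test_nonmonotone_dh_restricted_and_flagged(self):
        ds = TestSections()._clim()
        sec = extract_section(ds, 30.0)
        lat = sec["lat"].values
        dh = 1.0 + 0.08 * (lat + 50.0)
        dh[5] = dh[3]- 0.01                          # interior reversal
        out = to_dh_coordinate(sec, dh)
        assert len(out.attrs["excluded_lats"]) >= 1

    def test_empty_overlap_rejected(self):
        ds = TestSections()._clim()
        sec = extract_section(ds, 30.0)
        lat = sec["lat"].values
        a = to_dh_coordinate(sec, np.linspace(0.0, 1.0, lat.size))
        b = to_dh_coordinate(sec, np.linspace(5.0, 6.0, lat.size))
        with pytest.raises(ValueError, match="overlap"):
            alongstream_delta_sigma(a, b, lat, np.linspace(0, 1, lat.size))


class TestEndToEndRecovery:
    """Generator-truth recovery through the full gridding chain (reduced
    problem size; the acceptance suite runs the full configuration)."""

    def _run(self, tilt, meander, seed, n=900, noise=0.01):
        levels = standard_levels(50.0)              # coarser vertical grid
        glon = np.arange(20.0, 46.01, 0.5)
        glat = np.arange(-55.0, -44.99, 0.5)
        region = (8.0, 58.0, -68.0, -32.0)
        profs, dh, truth = synthetic.gen_hydrography(
            tilt=tilt, meander_deg=meander, n_profiles=n, region=region,
            noise_sd=noise, seed=seed)
        lons, lats, sigma = bin_profiles_vertical(profs, levels)
        ds = optimal_interpolation(lons, lats, sigma, glon, glat, levels)
        w = extract_section(ds, 28.0)
        e = extract_section(ds, 38.0)
        dh_w = dh.interp(lon=28.0).sel(lat=w["lat"].values).values
        dh_e = dh.interp(lon=38.0).sel(lat=e["lat"].values).values
        sector = dh.sel(lon=slice(28.0, 38.0))
        res = alongstream_delta_sigma(
            to_dh_coordinate(e, dh_e), to_dh_coordinate(w, dh_w),
            sector["lat"].values, sector.mean("lon").values)
        return res, truth

    def test_tilt_recovered_at_peak_pressure(self):
        res, truth = self._run(0.2, 0.0, seed=13)
        d = res.delta_sigma_dh.sel(pressure=750.0).values
        assert np.nanmean(d) == pytest.approx(truth.delta_sigma_peak_true,
                                              rel=0.15)

    def test_meander_invisible_in_dh_coordinate(self):
        res, _ = self._run(0.0, 2.0, seed=14)
        assert float(np.nanmax(np.abs(res.delta_sigma_dh.values))) < 0.03

    def test_shuffled_profile_order_identical(self):
        levels = standard_levels(100.0)
        profs, dh, _ = synthetic.gen_hydrography(n_profiles=80, seed=5)
        glon = np.arange(26.0, 40.1, 1.0)
        glat = np.arange(-52.0, -47.9, 1.0)
        l1, a1, s1 = bin_profiles_vertical(profs, levels)
        rng = np.random.default_rng(0)
        shuffled = list(profs)
        rng.shuffle(shuffled)
        l2, a2, s2 = bin_profiles_vertical(shuffled, levels)
        d1 = optimal_interpolation(l1, a1, s1, glon, glat, levels)
        d2 = optimal_interpolation(l2, a2, s2, glon, glat, levels)
        np.testing.assert_allclose(d1["sigma"].values, d2["sigma"].values,
                                   rtol=1e-12, equal_nan=True)
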