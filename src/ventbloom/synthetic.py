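"""Synthetic-data generators with prescribed ground truth.

Every input kind the pipeline consumes can be generated here with known
truth, so each downstream stage has a parameter-recovery test:

* float profile series with a prescribed bloom (Gaussian in time,
  exponential in depth inside a prescribed mixed layer), factory-calibrated
  fluorescence counts that overestimate truth by 1/F490, and daytime
  quenching in the light-exposed upper mixed layer;
* gridded velocity series (solid-body rotation, zonal jet, jet plus a
  propagating eddy train of known analytic EKE);
* ANDRO-like deep displacements whose binned velocity variance is the
  prescribed deep EKE;
* hydrographic profiles with an analytic alongstream density tilt (and an
  optional pure meander) plus a consistent dynamic-height field;
* delta-3He stations sampling an analytic hydrothermal plume;
* an analytic ridge-plus-shelf bathymetry.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import xarray as xr

from .climatology import HydroProfile
from .config import CalibrationSpec
from .fields import VelocityFieldSeries, to_hours
from .profiles import FloatProfile
from . import seawater

EARTH_RADIUS_M = 6_371_000.0
_DEG2M = math.pi / 180.0 * EARTH_RADIUS_M


@dataclass
class SyntheticTruth:
    """Ground-truth ledger accompanying each generated fixture."""

    rng_seed: int
    bloom_magnitude_true: Optional[float] = None     # mg m^-2
    mld_true: Optional[float] = None                 # m
    eke_true: Optional[float] = None                 # cm^2 s^-2
    delta_sigma_peak_true: Optional[float] = None    # kg m^-3 at the shape peak
    delta_sigma_peak_pres: Optional[float] = None    # dbar
    plume_peak_delta3he: Optional[float] = None      # percent
    flow_description: Optional[str] = None
    extras: Dict[str, object] = field(default_factory=dict)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        extras = d.pop("extras")
        d.update(extras)
        return json.dumps({k: v for k, v in d.items() if v is not None},
                          indent=2, sort_keys=True)


def _validate_finite(**params):
    for name, val in params.items():
        if not np.all(np.isfinite(val)):
            raise ValueError(f"parameter {name} must be finite, got {val}")


# ---------------------------------------------------------------------------
# float profile series

def gen_float_series(n_seasons: int = 1,
                     bloom_magnitude: float = 80.0,
                     bloom_center_days: float = 130.0,
                     bloom_time_sd_days: float = 40.0,
                     bloom_depth_scale: float = 300.0,
                     mld: float = 100.0,
                     noise_sd: float = 0.0,
                     quench_fraction: float = 0.0,
                     quench_depth_fraction: float = 0.3,
                     cal: Optional[CalibrationSpec] = None,
                     seed: int = 0,
                     cadence_days: float = 10.0,
                     depth_step: float = 5.0,
                     depth_max: float = 250.0,
                     start_year: int = 2014,
                     float_id: str = "SYN0001",
                     lon0: float = 30.0,
                     lat0: float = -50.0,
                     drift_deg_per_profile: float = 0.08,
                     ) -> Tuple[List[FloatProfile], SyntheticTruth]:
    """Float-profile series carrying a prescribed bloom.

    The chlorophyll field is C(z, t) = c0(t) * exp(-z / D) for z <= MLD and
    zero below, with c0(t) Gaussian in time (centre ``bloom_center_days``
    after 1 July, scale ``bloom_time_sd_days``) scaled so that the vertical
    integral peaks at ``bloom_magnitude`` mg m^-2.  Daytime casts have
    values above ``quench_depth_fraction * MLD`` multiplied by
    (1 - quench_fraction): light-driven quenching confined to the upper
    mixed layer, which is what the max-above-MLD extrapolation corrects.

    Fluorescence counts are chl / (F490_true * slope) + dark, i.e. the
    factory calibration overestimates truth by 1/F490.  T and S realise a
    mixed layer of prescribed depth: sigma-0 is constant down to MLD - 5 m,
    then increases at 0.006 kg m^-3 per m, so the 0.03 kg m^-3 threshold
    from the 10 m reference is crossed exactly at the MLD.
    """
    cal = cal or CalibrationSpec()
    cal.validate()
    _validate_finite(bloom_magnitude=bloom_magnitude, mld=mld,
                     bloom_time_sd_days=bloom_time_sd_days,
                     bloom_depth_scale=bloom_depth_scale, noise_sd=noise_sd,
                     quench_fraction=quench_fraction)
    if not (0.0 <= quench_fraction <= 1.0):
        raise ValueError("quench_fraction must lie in [0, 1]")
    if min(bloom_magnitude, mld, bloom_time_sd_days, bloom_depth_scale) <= 0:
        raise ValueError("bloom parameters must be strictly positive")

    rng = np.random.default_rng(seed)
    z = np.arange(depth_step, depth_max + depth_step / 2, depth_step)
    z_eff = bloom_depth_scale * (1.0 - math.exp(-mld / bloom_depth_scale))
    c0_peak = bloom_magnitude / z_eff
    q_depth = quench_depth_fraction * mld

    # density structure: mixed to (mld - 5), then 0.006 kg m^-3 per m, so
    # sigma(mld) = sigma_surface + 0.03 exactly
    sigma_surf = 26.70
    grad = 0.006
    kink = mld - 5.0
    pycno_bottom = mld + 20.0       # sharp pycnocline, then weak deep gradient
    sigma_z = sigma_surf + np.where(
        z <= kink, 0.0,
        np.where(z <= pycno_bottom, grad * (z - kink),
                 grad * (pycno_bottom - kink) + 0.0015 * (z - pycno_bottom)))
    psal = np.full(z.size, 34.0)
    theta = seawater.potential_temperature_from_sigma0(sigma_z, psal)
    temp = seawater.potential_temperature(psal, theta, 0.0, z)   # in-situ at depth

    profiles: List[FloatProfile] = []
    day = True
    for season in range(n_seasons):
        t_start = pd.Timestamp(year=start_year + season, month=7, day=1)
        n_prof = int(365 // cadence_days)
        for k in range(n_prof):
            t_days = k * cadence_days
            t = t_start + pd.Timedelta(days=float(t_days))
            c0 = c0_peak * math.exp(-((t_days - bloom_center_days) ** 2)
                                    / (2.0 * bloom_time_sd_days ** 2))
            chl = np.where(z <= mld, c0 * np.exp(-z / bloom_depth_scale), 0.0)
            if day and quench_fraction > 0:
                chl = np.where(z < q_depth, chl * (1.0 - quench_fraction), chl)
            if noise_sd > 0:
                chl = chl + rng.normal(0.0, noise_sd, size=z.size)
            fluo = chl / (cal.f490 * cal.slope) + cal.dark
            bbp = 3.0e-4 + 2.0e-3 * np.clip(chl, 0.0, None)
            lon = lon0 + drift_deg_per_profile * (k + season * n_prof)
            lat = lat0 + 0.3 * math.sin(0.13 * (k + season * n_prof))
            profiles.append(FloatProfile(
                float_id=float_id, cycle=season * n_prof + k + 1, time=t,
                lat=lat, lon=lon % 360.0, day_flag=day,
                pres=z, temp=temp, psal=psal, fluo=fluo, bbp700=bbp))
            day = not day
    truth = SyntheticTruth(
        rng_seed=seed, bloom_magnitude_true=bloom_magnitude, mld_true=mld,
        flow_description="prescribed bloom: Gaussian(time) x exp(-z/D) in ML",
        extras={"bloom_center_days": bloom_center_days,
                "bloom_time_sd_days": bloom_time_sd_days,
                "bloom_depth_scale_m": bloom_depth_scale,
                "quench_fraction": quench_fraction,
                "f490_true": cal.f490})
    return profiles, truth


# ---------------------------------------------------------------------------
# velocity fields

class AnalyticSolidBodyField:
    """Exact solid-body rotation for advection-scheme error analysis.

    In the scaled plane X = (lon - lon_c) cos(lat_c), Y = lat - lat_c the
    trajectory ODE reduces exactly to X' = -omega Y, Y' = omega X, so orbits
    are circles of known period 2 pi / omega: the one-period return error of
    the integrator measures pure scheme error (no grid interpolation).
    Exposes the same ``interp(lon, lat, t_h)`` surface as a gridded series.
    """

    def __init__(self, lon_c: float, lat_c: float, period_days: float = 30.0):
        self.lon_c = lon_c
        self.lat_c = lat_c
        self.omega = 2.0 * math.pi / (period_days * 86400.0)   # rad s^-1
        self._coslatc = math.cos(math.radians(lat_c))

    def velocity(self, lon: float, lat: float):
        X = (lon - self.lon_c) * self._coslatc
        Y = lat - self.lat_c
        u = -self.omega * Y * _DEG2M * math.cos(math.radians(lat)) / self._coslatc
        v = self.omega * X * _DEG2M
        return u, v

    def interp(self, lon: float, lat: float, t_h: float):
        return self.velocity(lon, lat)

    def covers(self, lon, lat):
        return True


def gen_velocity_series(kind: str = "zonal_jet",
                        params: Optional[dict] = None,
                        lon: Tuple[float, float, float] = (20.0, 45.0, 1.0),
                        lat: Tuple[float, float, float] = (-56.0, -44.0, 1.0),
                        n_times: int = 80,
                        dt_hours: float = 24.0,
                        t0: str = "2014-11-01",
                        seed: int = 0,
                        ) -> Tuple[VelocityFieldSeries, SyntheticTruth]:
    """Gridded velocity series of a named analytic flow.

    kinds: ``uniform`` (params U, V m/s),
    ``solid_body`` (params center=(lon, lat), period_days),
    ``zonal_jet`` (params U m/s, lat0, width_deg),
    ``jet_plus_eddies`` (jet params plus amplitude m/s, wavelength_deg,
    period_days): a propagating eddy train adding a sinusoid of amplitude A
    to both components, so the true surface EKE is A^2/2 (in m^2 s^-2;
    10^4 A^2/2 cm^2 s^-2).
    """
    params = dict(params or {})
    lons = np.arange(lon[0], lon[1] + lon[2] / 2, lon[2])
    lats = np.arange(lat[0], lat[1] + lat[2] / 2, lat[2])
    t_h = to_hours(pd.Timestamp(t0)) + np.arange(n_times) * dt_hours
    glat, glon = np.meshgrid(lats, lons, indexing="ij")
    u = np.zeros((n_times, lats.size, lons.size))
    v = np.zeros_like(u)
    truth = SyntheticTruth(rng_seed=seed)

    if kind == "uniform":
        u[:] = params.get("U", 0.1)
        v[:] = params.get("V", 0.0)
        truth.eke_true = 0.0
        truth.flow_description = (f"uniform U={params.get('U', 0.1)} "
                                  f"V={params.get('V', 0.0)}")
    elif kind == "solid_body":
        center = params.get("center", (float(np.mean(lons)), float(np.mean(lats))))
        period = params.get("period_days", 30.0)
        fldobj = AnalyticSolidBodyField(center[0], center[1], period)
        uu = np.empty_like(glat)
        vv = np.empty_like(glat)
        for j in range(lats.size):
            for i in range(lons.size):
                uu[j, i], vv[j, i] = fldobj.velocity(glon[j, i], glat[j, i])
        u[:] = uu
        v[:] = vv
        truth.flow_description = (f"solid_body center={center} "
                                  f"period_days={period}")
        truth.eke_true = 0.0
    elif kind in ("zonal_jet", "jet_plus_eddies"):
        U = params.get("U", 0.25)
        lat_j = params.get("lat0", float(np.mean(lats)))
        width = params.get("width_deg", 2.0)
        jet = U / np.cosh((glat - lat_j) / width) ** 2
        u[:] = jet
        truth.eke_true = 0.0
        truth.flow_description = f"zonal_jet U={U} lat0={lat_j} width={width}"
        if kind == "jet_plus_eddies":
            A = params.get("amplitude", 0.15)
            wavelength = params.get("wavelength_deg", 6.0)
            period = params.get("period_days", 8.0)
            if wavelength > (lon[1] - lon[0]):
                raise ValueError("domain too small for the requested eddies")
            kx = 2.0 * math.pi / wavelength
            omt = 2.0 * math.pi / (period * 24.0)       # per hour
            for n in range(n_times):
                ph = kx * (glon - lons[0]) - omt * (t_h[n] - t_h[0])
                u[n] += A * np.sin(ph)
                v[n] += A * np.cos(ph)
            truth.eke_true = 1.0e4 * A ** 2 / 2.0      # cm^2 s^-2
            truth.flow_description += (f" + eddies A={A} "
                                       f"wavelength={wavelength} period={period}")
    else:
        raise ValueError(f"unknown velocity kind {kind!r}")

    series = VelocityFieldSeries(time_h=t_h, lat=lats, lon=lons, u=u, v=v)
    return series, truth


# ---------------------------------------------------------------------------
# deep displacements

def gen_displacements(n: int = 10_000,
                      mean_flow: Tuple[float, float] = (0.0, 0.0),
                      noise_sd: float = 0.1,
                      region: Tuple[float, float, float, float] = (30.0, 31.0, -50.0, -49.0),
                      cycle_days: float = 10.0,
                      park_pres: float = 1000.0,
                      t_start: str = "2005-01-01",
                      seed: int = 0,
                      ) -> Tuple[pd.DataFrame, SyntheticTruth]:
    """ANDRO-like displacement records with prescribed deep EKE.

    Per-cycle velocity = mean_flow + isotropic Gaussian noise (sd
    ``noise_sd`` m/s per component), so the true deep EKE is noise_sd^2 in
    m^2 s^-2 (10^4 noise_sd^2 cm^2 s^-2).  Endpoints are built by inverting
    the local-tangent midpoint formula, making the derived velocities exact.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    _validate_finite(noise_sd=noise_sd, cycle_days=cycle_days)
    rng = np.random.default_rng(seed)
    lon_min, lon_max, lat_min, lat_max = region
    # displacement midpoints sampled uniformly in the region, so the derived
    # velocity-at-midpoint samples are positioned independently of velocity
    lonm = rng.uniform(lon_min, lon_max, n)
    latm = rng.uniform(lat_min, lat_max, n)
    u = mean_flow[0] + (rng.normal(0.0, noise_sd, n) if noise_sd > 0 else 0.0)
    v = mean_flow[1] + (rng.normal(0.0, noise_sd, n) if noise_sd > 0 else 0.0)
    dt_s = cycle_days * 86400.0
    dlat = v * dt_s / _DEG2M
    lat0, lat1 = latm - dlat / 2.0, latm + dlat / 2.0
    dlon = u * dt_s / (_DEG2M * np.cos(np.radians(latm)))
    lon0, lon1 = lonm - dlon / 2.0, lonm + dlon / 2.0
    t0 = pd.Timestamp(t_start) + pd.to_timedelta(
        rng.integers(0, 3000, n) * 24.0, unit="h")
    df = pd.DataFrame({
        "float_id": [f"A{k % 97:04d}" for k in range(n)],
        "cycle": np.arange(1, n + 1),
        "park_pres_dbar": park_pres,
        "t0": t0, "lon0": lon0, "lat0": lat0,
        "t1": t0 + pd.Timedelta(days=cycle_days), "lon1": lon1, "lat1": lat1})
    truth = SyntheticTruth(rng_seed=seed, eke_true=1.0e4 * noise_sd ** 2,
                           flow_description=(f"mean_flow={mean_flow} "
                                             f"noise_sd={noise_sd} m/s"))
    return df, truth


# ---------------------------------------------------------------------------
# hydrography + dynamic height

def _sigma_field(pres, lat_eff, lon, tilt, lon_ref, shape_peak_pres, shape_sd):
    """Analytic potential-density field: stratified background + meridional
    gradient + alongstream tilt localised in pressure."""
    background = 26.2 + 1.6 * (1.0 - np.exp(-np.asarray(pres) / 700.0))
    eta = -(np.asarray(lat_eff)) - 50.0        # positive southward of 50S
    # ACC-like density front centred on the (possibly meandering) 50S line
    merid = 0.25 * np.tanh(eta / 3.0)
    shape = np.exp(-((np.asarray(pres) - shape_peak_pres) ** 2)
                   / (2.0 * shape_sd ** 2))
    along = tilt * (np.asarray(lon) - lon_ref) / 10.0 * shape
    return background + merid + along


def gen_hydrography(tilt: float = 0.2,
                    n_profiles: int = 1800,
                    region: Tuple[float, float, float, float] = (8.0, 58.0, -68.0, -32.0),
                    noise_sd: float = 0.01,
                    seed: int = 0,
                    meander_deg: float = 0.0,
                    lon_ref: float = 28.0,
                    shape_peak_pres: float = 750.0,
                    shape_sd_pres: float = 250.0,
                    sample_dp: float = 50.0,
                    p_max: float = 2000.0,
                    qc_bad_fraction: float = 0.03,
                    ) -> Tuple[List[HydroProfile], xr.DataArray, SyntheticTruth]:
    """Hydrographic profiles with an analytic alongstream density tilt.

    sigma(P, lat, lon) = background(P, lat_eff) +
    tilt * (lon - lon_ref)/10 deg * shape(P) + noise, the shape peaking at
    ``shape_peak_pres`` (default 750 dbar).  ``meander_deg`` displaces the
    whole meridional structure northward downstream
    (lat_eff = lat - meander_deg * (lon - lon_ref)/10) without any
    water-mass change; the companion dynamic-height field meanders
    identically, so in dh coordinate the meander is invisible and the
    alongstream density contrast at the shape peak is exactly ``tilt`` per
    10 degrees of longitude.

    The default sampling band (32-68 S) is deliberately much wider in
    latitude than the mapped analysis region: the Gaussian-mean mapping is
    biased wherever the sampling window is truncated within a decorrelation
    scale of the field's structure, and that bias does not cancel between
    sections when the front meanders relative to a narrow fixed window.

    Returns (profiles, dh grid DataArray(lat, lon), truth).  A fraction of
    profiles carries qc_flag = 4 to exercise QC filtering.
    """
    _validate_finite(tilt=tilt, noise_sd=noise_sd, meander_deg=meander_deg)
    rng = np.random.default_rng(seed)
    lon_min, lon_max, lat_min, lat_max = region
    lons = rng.uniform(lon_min, lon_max, n_profiles)
    lats = rng.uniform(lat_min, lat_max, n_profiles)
    pres = np.arange(0.0, p_max + sample_dp / 2, sample_dp)
    psal_profile = 34.0 + 1.6 * (1.0 - np.exp(-pres / 500.0))
    sources = np.array(["ship", "float", "animal"])

    profiles: List[HydroProfile] = []
    for k in range(n_profiles):
        lat_eff = lats[k] - meander_deg * (lons[k] - lon_ref) / 10.0
        sig = _sigma_field(pres, lat_eff, lons[k], tilt, lon_ref,
                           shape_peak_pres, shape_sd_pres)
        if noise_sd > 0:
            sig = sig + rng.normal(0.0, noise_sd, pres.size)
        sig = np.maximum.accumulate(sig)      # keep each cast stably stratified
        theta = seawater.potential_temperature_from_sigma0(sig, psal_profile)
        temp = seawater.potential_temperature(psal_profile, theta, 0.0, pres)
        qc = 4 if rng.uniform() < qc_bad_fraction else 1
        profiles.append(HydroProfile(
            profile_id=f"H{k:05d}", source=str(rng.choice(sources)), qc_flag=qc,
            time=pd.Timestamp("2008-01-01") + pd.Timedelta(days=float(rng.integers(0, 3650))),
            lat=lats[k], lon=lons[k], pres=pres, temp=temp, psal=psal_profile))

    # dynamic height: monotone in effective latitude, meandering with the front
    glat = np.arange(lat_min, lat_max + 0.25, 0.5)
    glon = np.arange(lon_min, lon_max + 0.25, 0.5)
    mlat, mlon = np.meshgrid(glat, glon, indexing="ij")
    lat_eff_g = mlat - meander_deg * (mlon - lon_ref) / 10.0
    dh = 1.0 + 0.08 * (lat_eff_g + 50.0)       # dyn m, increasing northward
    dh_da = xr.DataArray(dh, coords={"lat": glat, "lon": glon},
                         dims=("lat", "lon"), name="dh")
    truth = SyntheticTruth(
        rng_seed=seed, delta_sigma_peak_true=tilt,
        delta_sigma_peak_pres=shape_peak_pres,
        flow_description=(f"tilt={tilt} kg m-3 per 10 deg lon, "
                          f"meander={meander_deg} deg"),
        extras={"noise_sd": noise_sd, "lon_ref": lon_ref,
                "shape_sd_pres": shape_sd_pres})
    return profiles, dh_da, truth


# ---------------------------------------------------------------------------
# tracer stations

def gen_tracer_stations(stations: Sequence[Tuple[float, float]],
                        plume_center_depth: float = 1500.0,
                        plume_peak: float = 12.0,
                        plume_depth_sd: float = 500.0,
                        decay_scale_km: float = 1500.0,
                        ridge_lon: float = 25.0,
                        background: float = 1.0,
                        thermocline_depth: float = 500.0,
                        depth_max: float = 3500.0,
                        depth_step: float = 100.0,
                        seed: int = 0,
                        noise_sd: float = 0.0,
                        cruise: str = "SYNHE01",
                        ) -> Tuple[pd.DataFrame, SyntheticTruth]:
    """delta-3He stations sampling an analytic hydrothermal plume.

    The plume is Gaussian in depth about ``plume_center_depth`` with
    amplitude ``plume_peak`` percent at the ridge longitude, decaying
    exponentially only downstream (east) of ``ridge_lon``; west of the
    ridge stations see background only.  Above ``thermocline_depth`` the
    anomaly is suppressed toward background (atmospheric exchange).
    """
    if not len(stations):
        raise ValueError("stations must be nonempty")
    _validate_finite(plume_peak=plume_peak, decay_scale_km=decay_scale_km)
    rng = np.random.default_rng(seed)
    depths = np.arange(0.0, depth_max + depth_step / 2, depth_step)
    rows = []
    for k, (lat, lon) in enumerate(stations):
        east_km = ((lon - ridge_lon) * math.cos(math.radians(lat))
                   * _DEG2M / 1000.0)
        amp = math.exp(-east_km / decay_scale_km) if east_km >= 0 else 0.0
        gz = np.exp(-((depths - plume_center_depth) ** 2)
                    / (2.0 * plume_depth_sd ** 2))
        supp = np.where(depths < thermocline_depth,
                        np.exp(-(thermocline_depth - depths) / 150.0), 1.0)
        vals = background + (plume_peak - background) * amp * gz * supp
        if noise_sd > 0:
            vals = vals + rng.normal(0.0, noise_sd, depths.size)
        for z, v in zip(depths, vals):
            rows.append({"cruise": cruise, "station": f"S{k:03d}",
                         "lat": lat, "lon": lon, "depth_m": z,
                         "delta3He_pct": v})
    df = pd.DataFrame(rows)
    truth = SyntheticTruth(
        rng_seed=seed, plume_peak_delta3he=plume_peak,
        flow_description=(f"plume center {plume_center_depth} m, "
                          f"ridge at {ridge_lon}E, decay {decay_scale_km} km"),
        extras={"plume_center_depth_m": plume_center_depth,
                "background_pct": background})
    return df, truth


# ---------------------------------------------------------------------------
# bathymetry

def gen_bathymetry(region: Tuple[float, float, float, float] = (8.0, 58.0, -56.0, -44.0),
                   res_deg: float = 0.25,
                   ridge_lon: float = 30.0,
                   ridge_width_deg: float = 3.0,
                   crest_depth: float = 1400.0,
                   abyss_depth: float = 4000.0,
                   shelf_lon_width: float = 2.0,
                   shelf_depth: float = 300.0,
                   ) -> xr.DataArray:
    """Analytic bathymetry: a Gaussian mid-ocean ridge (crest shallower than
    2000 m) on an abyssal plain, plus a shelf shallower than 500 m at the
    western domain edge to provide a shallow-bathymetry iron source."""
    lon_min, lon_max, lat_min, lat_max = region
    glon = np.arange(lon_min, lon_max + res_deg / 2, res_deg)
    glat = np.arange(lat_min, lat_max + res_deg / 2, res_deg)
    mlat, mlon = np.meshgrid(glat, glon, indexing="ij")
    ridge = (abyss_depth - crest_depth) * np.exp(
        -((mlon - ridge_lon) ** 2) / (2.0 * ridge_width_deg ** 2))
    shelf = (abyss_depth - shelf_depth) * np.exp(
        -((mlon - lon_min) ** 2) / (2.0 * shelf_lon_width ** 2))
    depth = abyss_depth - np.maximum(ridge, shelf)
    return xr.DataArray(depth, coords={"lat": glat, "lon": glon},
                        dims=("lat", "lon"), name="depth_m",
                        attrs={"units": "m", "positive": "down"})


# ---------------------------------------------------------------------------
# bloom-magnitude population (for type comparison statistics)

def gen_bloom_magnitudes(means: Optional[Dict[str, float]] = None,
                         n_per_type: int = 20, sd: float = 15.0,
                         seed: int = 0) -> pd.DataFrame:
    """Per-type bloom-magnitude draws mimicking the observed type ordering
    (island/plateau ~98.1, ice ~70.0, HNLC ~42.0 mg m^-2)."""
    means = means or {"island_plateau": 98.1, "ice": 70.0, "HNLC": 42.0}
    rng = np.random.default_rng(seed)
    rows = []
    for btype, mu in means.items():
        for val in rng.normal(mu, sd, n_per_type):
            rows.append({"bloom_type": btype, "magnitude_mg_m2": max(val, 1.0)})
    return pd.DataFrame(rows)
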