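"""Eddy kinetic energy from float displacements and gridded velocities.

Deep EKE follows the Argo-displacement approach: each float cycle's deep
displacement yields one velocity sample at parking depth; samples are binned
into 1 deg x 1 deg boxes; per box the time-mean is removed and
EKE = (var(u') + var(v')) / 2 in cm^2 s^-2, keeping only boxes with strictly
more than ``min_count`` samples.  The coarse field is then spread onto a
finer grid with a count-weighted Gaussian correlation kernel
(exp(-d^2 / 2 r^2), r = 100 km by default).

Surface EKE is computed pointwise from a gridded velocity time series as the
time mean of half the squared velocity anomalies.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .fields import VelocityFieldSeries

log = logging.getLogger("ventbloom")

EARTH_RADIUS_M = 6_371_000.0
_MIN_DT_S = 86400.0   # displacements spanning less than one day are rejected


def displacement_velocity(lon0, lat0, t0, lon1, lat1, t1):
    """Velocity (u, v) in cm s^-1 from a deep displacement record.

    Local-tangent conversion at the mean latitude:
    u = dlon * cos(latbar) * (pi/180) * R / dt, v = dlat * (pi/180) * R / dt.
    Raises ValueError when the elapsed time is under one day.
    """
    dt = (pd.Timestamp(t1) - pd.Timestamp(t0)).total_seconds()
    if dt < _MIN_DT_S:
        raise ValueError(f"displacement spans {dt:.0f} s < 1 day")
    dlon = (lon1 - lon0 + 180.0) % 360.0 - 180.0
    dlat = lat1 - lat0
    latbar = 0.5 * (lat0 + lat1)
    meters_per_deg = np.pi / 180.0 * EARTH_RADIUS_M
    u = dlon * np.cos(np.radians(latbar)) * meters_per_deg / dt
    v = dlat * meters_per_deg / dt
    return 100.0 * u, 100.0 * v


def velocities_from_displacements(df: pd.DataFrame) -> pd.DataFrame:
    """Per-record velocities (cm s^-1) at displacement midpoints.

    Records spanning less than one day are dropped and logged.
    """
    rows = []
    n_rej = 0
    for rec in df.itertuples(index=False):
        try:
            u, v = displacement_velocity(rec.lon0, rec.lat0, rec.t0,
                                         rec.lon1, rec.lat1, rec.t1)
        except ValueError:
            n_rej += 1
            continue
        dlon = (rec.lon1 - rec.lon0 + 180.0) % 360.0 - 180.0
        rows.append({"lon": (rec.lon0 + 0.5 * dlon) % 360.0,
                     "lat": 0.5 * (rec.lat0 + rec.lat1), "u": u, "v": v})
    if n_rej:
        log.info("rejected %d displacement records with dt < 1 day", n_rej)
    return pd.DataFrame(rows, columns=["lon", "lat", "u", "v"])


def bin_deep_eke(velocities: pd.DataFrame, bin_deg: float = 1.0,
                 min_count: int = 5) -> xr.Dataset:
    """Bin velocity samples into boxes and form EKE = (var u' + var v')/2.

    Population (1/n) variances realise the time-average overbar.  Boxes with
    count <= ``min_count`` are masked (NaN).  Units cm^2 s^-2.
    """
    if velocities.empty:
        raise ValueError("no velocity samples")
    df = velocities.copy()
    df["ilon"] = np.floor(df["lon"] / bin_deg).astype(int)
    df["ilat"] = np.floor(df["lat"] / bin_deg).astype(int)
    g = df.groupby(["ilat", "ilon"])
    stats = g.agg(mean_u=("u", "mean"), mean_v=("v", "mean"),
                  var_u=("u", lambda x: np.var(x)),
                  var_v=("v", lambda x: np.var(x)),
                  count=("u", "size")).reset_index()

    ilat = np.arange(stats["ilat"].min(), stats["ilat"].max() + 1)
    ilon = np.arange(stats["ilon"].min(), stats["ilon"].max() + 1)
    shape = (ilat.size, ilon.size)
    arrays = {k: np.full(shape, np.nan) for k in
              ("mean_u", "mean_v", "var_u", "var_v", "eke")}
    counts = np.zeros(shape, dtype=int)
    r = stats["ilat"].to_numpy() - ilat[0]
    c = stats["ilon"].to_numpy() - ilon[0]
    counts[r, c] = stats["count"]
    keep = stats["count"].to_numpy() > min_count
    for k in ("mean_u", "mean_v", "var_u", "var_v"):
        vals = np.where(keep, stats[k].to_numpy(), np.nan)
        arrays[k][r, c] = vals
    arrays["eke"] = 0.5 * (arrays["var_u"] + arrays["var_v"])

    coords = {"lat": ("lat", (ilat + 0.5) * bin_deg),
              "lon": ("lon", (ilon + 0.5) * bin_deg)}
    ds = xr.Dataset(
        {k: (("lat", "lon"), v) for k, v in arrays.items()}
        | {"count": (("lat", "lon"), counts)},
        coords=coords)
    ds["eke"].attrs["units"] = "cm2 s-2"
    ds.attrs["bin_deg"] = bin_deg
    ds.attrs["min_count"] = min_count
    return ds


def great_circle_km(lon0, lat0, lon1, lat1):
    """Haversine great-circle distance in km (broadcasting)."""
    p0, p1 = np.radians(lat0), np.radians(lat1)
    dphi = p1 - p0
    dlmb = np.radians(np.asarray(lon1) - np.asarray(lon0))
    a = np.sin(dphi / 2) ** 2 + np.cos(p0) * np.cos(p1) * np.sin(dlmb / 2) ** 2
    return 2 * EARTH_RADIUS_M / 1000.0 * np.arcsin(np.minimum(1.0, np.sqrt(a)))


def smooth_eke(grid: xr.Dataset, radius_km: float = 100.0,
               fine_res_deg: float = 0.25, weight_floor: float = 1e-3
               ) -> xr.DataArray:
    """Spread binned EKE onto a finer grid with a count-weighted Gaussian.

    Node value = sum_i w_i eke_i / sum_i w_i with
    w_i = count_i * exp(-d_i^2 / (2 radius^2)), the sum running over unmasked
    boxes; nodes where sum w_i < ``weight_floor`` are missing.  The result is
    a convex combination of box values.
    """
    eke = grid["eke"].values
    ok = np.isfinite(eke)
    if not ok.any():
        warnings.warn("all EKE boxes masked; smoothed field is empty")
    blat, blon = np.meshgrid(grid["lat"].values, grid["lon"].values, indexing="ij")
    src_lon = blon[ok]
    src_lat = blat[ok]
    src_eke = eke[ok]
    src_cnt = grid["count"].values[ok].astype(float)

    flat = np.arange(grid["lat"].values.min() - 0.5, grid["lat"].values.max() + 0.5001,
                     fine_res_deg)
    flon = np.arange(grid["lon"].values.min() - 0.5, grid["lon"].values.max() + 0.5001,
                     fine_res_deg)
    out = np.full((flat.size, flon.size), np.nan)
    if src_eke.size:
        glat, glon = np.meshgrid(flat, flon, indexing="ij")
        d = great_circle_km(glon[..., None], glat[..., None], src_lon, src_lat)
        w = src_cnt * np.exp(-d ** 2 / (2.0 * radius_km ** 2))
        wsum = w.sum(axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = (w * src_eke).sum(axis=-1) / wsum
        out = np.where(wsum >= weight_floor, vals, np.nan)
    da = xr.DataArray(out, coords={"lat": flat, "lon": flon}, dims=("lat", "lon"),
                      name="eke_smoothed", attrs={"units": "cm2 s-2",
                                                  "radius_km": radius_km})
    return da


def surface_eke(series: VelocityFieldSeries) -> xr.DataArray:
    """Surface EKE (cm^2 s^-2) per grid node from a velocity time series.

    u' = u - time-mean(u), likewise v'; EKE = time-mean of (u'^2 + v'^2)/2.
    A single time slice yields a zero field with a warning.
    """
    u = series.u
    v = series.v
    if series.time_h.size < 2:
        warnings.warn("single time slice: surface EKE is identically zero")
        eke = np.zeros(u.shape[1:])
    else:
        up = u - np.nanmean(u, axis=0)
        vp = v - np.nanmean(v, axis=0)
        eke = np.nanmean(0.5 * (up ** 2 + vp ** 2), axis=0)
    eke = eke * 1.0e4   # m^2 s^-2 -> cm^2 s^-2
    return xr.DataArray(eke, coords={"lat": series.lat, "lon": series.lon},
                        dims=("lat", "lon"), name="eke",
                        attrs={"units": "cm2 s-2"})
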