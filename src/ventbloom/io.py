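"""Readers and writers for the pipeline's file formats.

Formats covered (all plain text or NetCDF3-classic via the scipy backend):

* float profiles — minimal Argo-dialect NetCDF (PRES/TEMP/PSAL/
  CHLA_FLUORESCENCE/BBP700, adjusted variables preferred when present) and a
  one-row-per-level CSV fixture dialect;
* gridded velocity series (time, lat, lon; u, v in m s^-1, cm s^-1
  converted on read);
* ANDRO-like deep-displacement CSV;
* hydrographic-profile CSV (T/S/P with position/date/QC flag);
* GLODAP-like delta-3He station CSV;
* bathymetry and dynamic-height NetCDF grids.

Longitudes are normalised to [0, 360) at ingest.  Every writer/reader pair
round-trips its type to float precision.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .fields import VelocityFieldSeries, from_hours, to_hours
from .profiles import FloatProfile

log = logging.getLogger("ventbloom")

_TIME_UNITS = "hours since 2000-01-01 00:00:00"


class FormatError(ValueError):
    """Malformed input file."""


def normalize_lon(lon):
    """Normalise longitudes to [0, 360)."""
    return np.mod(np.asarray(lon, dtype=float), 360.0)


# ---------------------------------------------------------------------------
# float profiles

PROFILE_CSV_COLUMNS = ["float_id", "cycle", "time", "lat", "lon", "day_flag",
                       "pres_dbar", "temp_C", "psal", "fluo_counts", "bbp700_m-1"]


def write_profile_series_csv(profiles: Sequence[FloatProfile], path) -> None:
    rows = []
    for p in profiles:
        for k in range(p.n_levels):
            rows.append((p.float_id, p.cycle, p.time.isoformat(), p.lat, p.lon,
                         int(p.day_flag), p.pres[k], p.temp[k], p.psal[k],
                         p.fluo[k], p.bbp700[k]))
    df = pd.DataFrame(rows, columns=PROFILE_CSV_COLUMNS)
    df.to_csv(path, index=False, float_format="%.10g")


def _read_profile_csv(path) -> List[FloatProfile]:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty profile file")
        return []
    if df.empty:
        warnings.warn(f"{path}: empty profile file")
        return []
    missing = [c for c in PROFILE_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if "qc" in df.columns:
        df = df[df["qc"].astype(int) == 1]
    profiles = []
    for (fid, cyc), g in df.groupby(["float_id", "cycle"], sort=False):
        g = g.sort_values("pres_dbar")
        level_ok = np.isfinite(g[["pres_dbar", "temp_C", "psal"]].to_numpy()).all(axis=1)
        g = g[level_ok]
        if g.empty:
            continue
        if g["time"].nunique() > 1:
            raise FormatError(
                f"{path}: float {fid} cycle {cyc}: inconsistent cast time "
                f"(first offending record index {g.index[0]})")
        try:
            profiles.append(FloatProfile(
                float_id=str(fid), cycle=int(cyc),
                time=pd.Timestamp(g["time"].iloc[0]),
                lat=float(g["lat"].iloc[0]),
                lon=float(normalize_lon(g["lon"].iloc[0])),
                day_flag=bool(int(g["day_flag"].iloc[0])),
                pres=g["pres_dbar"].to_numpy(), temp=g["temp_C"].to_numpy(),
                psal=g["psal"].to_numpy(), fluo=g["fluo_counts"].to_numpy(),
                bbp700=g["bbp700_m-1"].to_numpy()))
        except ValueError as exc:
            raise FormatError(f"{path}: float {fid} cycle {cyc}: {exc}") from exc
    profiles.sort(key=lambda p: (p.time, p.float_id, p.cycle))
    return profiles


_ARGO_GOOD_QC = set("1258")


def _argo_pick(ds: xr.Dataset, name: str, iprof: int):
    """Prefer <NAME>_ADJUSTED when present and not all-missing, else <NAME>."""
    for cand in (f"{name}_ADJUSTED", name):
        if cand in ds:
            vals = np.asarray(ds[cand].values[iprof], dtype=float)
            if np.isfinite(vals).any():
                qc_name = cand + "_QC"
                if qc_name in ds:
                    qc = ds[qc_name].values[iprof]
                    qc = np.array([bytes([b]).decode() if isinstance(b, int) else
                                   (b.decode() if isinstance(b, bytes) else str(b))
                                   for b in np.ravel(qc)])
                    vals = np.where(np.isin(qc, list(_ARGO_GOOD_QC)), vals, np.nan)
                return vals
    return None


def _read_profile_argo(path) -> List[FloatProfile]:
    with xr.open_dataset(path, engine="scipy", decode_times=True) as ds:
        ds = ds.load()
    n_prof = ds.sizes.get("N_PROF")
    if n_prof is None or "PRES" not in ds:
        raise FormatError(f"{path}: not an Argo-dialect profile file (need N_PROF, PRES)")
    float_id = str(np.ravel(ds["PLATFORM_NUMBER"].values)[0]).strip() \
        if "PLATFORM_NUMBER" in ds else Path(path).stem
    profiles = []
    for i in range(n_prof):
        pres = _argo_pick(ds, "PRES", i)
        temp = _argo_pick(ds, "TEMP", i)
        psal = _argo_pick(ds, "PSAL", i)
        fluo = _argo_pick(ds, "CHLA_FLUORESCENCE", i)
        if fluo is None:
            fluo = _argo_pick(ds, "FLUORESCENCE_CHLA", i)
        bbp = _argo_pick(ds, "BBP700", i)
        if pres is None or temp is None or psal is None:
            raise FormatError(f"{path}: profile {i}: missing PRES/TEMP/PSAL")
        n = pres.size
        if fluo is None:
            fluo = np.full(n, np.nan)
        if bbp is None:
            bbp = np.full(n, np.nan)
        ok = np.isfinite(pres) & np.isfinite(temp) & np.isfinite(psal)
        if not ok.any():
            continue
        order = np.argsort(pres[ok], kind="stable")
        t = pd.Timestamp(np.ravel(ds["JULD"].values)[i])
        cyc = int(np.ravel(ds["CYCLE_NUMBER"].values)[i]) if "CYCLE_NUMBER" in ds else i
        day = True
        if "DAY_FLAG" in ds:
            day = bool(np.ravel(ds["DAY_FLAG"].values)[i])
        profiles.append(FloatProfile(
            float_id=float_id, cycle=cyc, time=t,
            lat=float(np.ravel(ds["LATITUDE"].values)[i]),
            lon=float(normalize_lon(np.ravel(ds["LONGITUDE"].values)[i])),
            day_flag=day,
            pres=pres[ok][order], temp=temp[ok][order], psal=psal[ok][order],
            fluo=fluo[ok][order], bbp700=bbp[ok][order]))
    profiles.sort(key=lambda p: (p.time, p.float_id, p.cycle))
    return profiles


def read_profile_series(path, dialect="fixture_csv") -> List[FloatProfile]:
    """Read a float profile series; ``dialect`` in {argo_netcdf, fixture_csv}."""
    if dialect == "fixture_csv":
        return _read_profile_csv(path)
    if dialect == "argo_netcdf":
        return _read_profile_argo(path)
    raise FormatError(f"unknown profile dialect: {dialect!r}")


# ---------------------------------------------------------------------------
# gridded velocity series

def write_velocity_series(series: VelocityFieldSeries, path) -> None:
    ds = xr.Dataset(
        {"u": (("time", "lat", "lon"), series.u, {"units": "m s-1"}),
         "v": (("time", "lat", "lon"), series.v, {"units": "m s-1"})},
        coords={"time": ("time", series.time_h, {"units": _TIME_UNITS}),
                "lat": ("lat", series.lat, {"units": "degrees_north"}),
                "lon": ("lon", series.lon, {"units": "degrees_east"})})
    ds.to_netcdf(path, engine="scipy")


def read_velocity_series(path) -> VelocityFieldSeries:
    with xr.open_dataset(path, engine="scipy", decode_times=False) as ds:
        ds = ds.load()
    for var in ("u", "v", "time", "lat", "lon"):
        if var not in ds:
            raise FormatError(f"{path}: missing variable {var!r}")
    time_units = ds["time"].attrs.get("units", _TIME_UNITS)
    t = np.asarray(ds["time"].values, dtype=float)
    if not time_units.startswith("hours since 2000-01-01"):
        raise FormatError(f"{path}: unsupported time units {time_units!r}")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise FormatError(f"{path}: time coordinate not strictly increasing")
    u = np.asarray(ds["u"].values, dtype=float)
    v = np.asarray(ds["v"].values, dtype=float)
    units = ds["u"].attrs.get("units", "m s-1").replace("/", " ").strip()
    if units.startswith("cm"):
        u = u * 0.01
        v = v * 0.01
    elif not units.startswith("m"):
        raise FormatError(f"{path}: unsupported velocity units {units!r}")
    try:
        return VelocityFieldSeries(time_h=t, lat=np.asarray(ds["lat"].values, float),
                                   lon=normalize_lon(ds["lon"].values), u=u, v=v)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# displacements (ANDRO-like)

DISPLACEMENT_COLUMNS = ["float_id", "cycle", "park_pres_dbar",
                        "t0", "lon0", "lat0", "t1", "lon1", "lat1"]


def write_displacements(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.10g",
              columns=DISPLACEMENT_COLUMNS)


def read_displacements(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in DISPLACEMENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df["t0"] = pd.to_datetime(df["t0"])
    df["t1"] = pd.to_datetime(df["t1"])
    bad = df.index[df["t1"] <= df["t0"]]
    if len(bad):
        raise FormatError(f"{path}: record {bad[0]}: t1 <= t0")
    for col in ("lon0", "lon1"):
        df[col] = normalize_lon(df[col])
    return df


# ---------------------------------------------------------------------------
# hydrography

HYDRO_COLUMNS = ["profile_id", "source", "qc_flag", "time", "lat", "lon",
                 "pres_dbar", "temp_C", "psal"]


def write_hydrography(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.10g", columns=HYDRO_COLUMNS)


def read_hydrography(path) -> pd.DataFrame:
    """One row per level; only qc_flag == 1 rows are retained."""
    df = pd.read_csv(path)
    missing = [c for c in HYDRO_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df = df[df["qc_flag"].astype(int) == 1].copy()
    df["lon"] = normalize_lon(df["lon"])
    return df


# ---------------------------------------------------------------------------
# tracer stations (GLODAP-like)

TRACER_COLUMNS = ["cruise", "station", "lat", "lon", "depth_m", "delta3He_pct"]


def write_tracer_stations(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.10g", columns=TRACER_COLUMNS)


def read_tracer_stations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRACER_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df["lon"] = normalize_lon(df["lon"])
    return df


# ---------------------------------------------------------------------------
# scalar grids (bathymetry, dynamic height, masks)

def write_grid(da: xr.DataArray, path, name: str) -> None:
    da = da.rename(name)
    da.to_dataset().to_netcdf(path, engine="scipy")


def read_grid(path, name: str) -> xr.DataArray:
    with xr.open_dataset(path, engine="scipy", decode_times=False) as ds:
        ds = ds.load()
    if name not in ds:
        raise FormatError(f"{path}: missing variable {name!r}")
    da = ds[name]
    if "lon" in da.coords:
        da = da.assign_coords(lon=normalize_lon(da["lon"].values))
    return da
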