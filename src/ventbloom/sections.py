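"""Helium-3 tracer sections.

delta-3He (percent deviation of the 3He/4He ratio from atmospheric) station
profiles are gridded into a vertical section: linear interpolation to a
common depth grid within each station, then linear interpolation between
stations along the cumulative great-circle track distance.  Linear (not
spline) interpolation keeps gridded values inside the range of the station
data, which matters for sparse tracer sampling.  Stations sitting in a
high-EKE environment (surface EKE above a threshold, 150 cm^2 s^-2 by
default) are flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .eke import great_circle_km


@dataclass
class TracerStation:
    cruise: str
    station: str
    lat: float
    lon: float
    depths: np.ndarray       # m, strictly increasing
    delta3he: np.ndarray     # percent

    def __post_init__(self):
        self.depths = np.asarray(self.depths, dtype=float)
        self.delta3he = np.asarray(self.delta3he, dtype=float)
        if self.depths.size >= 2 and not np.all(np.diff(self.depths) > 0):
            raise ValueError(f"station {self.station}: depths not strictly increasing")


def stations_from_frame(df: pd.DataFrame) -> List[TracerStation]:
    out = []
    for (cruise, station), g in df.groupby(["cruise", "station"], sort=False):
        g = g.sort_values("depth_m")
        out.append(TracerStation(cruise=str(cruise), station=str(station),
                                 lat=float(g["lat"].iloc[0]),
                                 lon=float(g["lon"].iloc[0]),
                                 depths=g["depth_m"].to_numpy(),
                                 delta3he=g["delta3He_pct"].to_numpy()))
    return out


def grid_section(stations: Sequence[TracerStation], depth_grid: np.ndarray
                 ) -> xr.Dataset:
    """Grid ordered stations into a (depth, along-track) section.

    Within each station delta-3He is linearly interpolated to ``depth_grid``
    (no extrapolation below the deepest sample); across stations linearly in
    cumulative great-circle distance.  A single station yields a one-column
    section with a warning.
    """
    if not stations:
        raise ValueError("no stations")
    if len(stations) == 1:
        warnings.warn("single station: section is one column")
    depth_grid = np.asarray(depth_grid, dtype=float)
    along = [0.0]
    for a, b in zip(stations[:-1], stations[1:]):
        along.append(along[-1] + float(great_circle_km(a.lon, a.lat, b.lon, b.lat)))
    along = np.asarray(along)

    cols = np.full((depth_grid.size, len(stations)), np.nan)
    for k, st in enumerate(stations):
        ok = np.isfinite(st.delta3he)
        if ok.sum() < 2:
            continue
        z, v = st.depths[ok], st.delta3he[ok]
        inside = (depth_grid >= z[0]) & (depth_grid <= z[-1])
        cols[inside, k] = np.interp(depth_grid[inside], z, v)

    # along-track linear interpolation onto the station track itself is the
    # identity; the gridded field simply carries the station columns plus
    # any finer along-track axis the caller interpolates to later.
    ds = xr.Dataset(
        {"delta3he": (("depth", "along_km"), cols, {"units": "percent"})},
        coords={"depth": ("depth", depth_grid, {"units": "m"}),
                "along_km": ("along_km", along),
                "station_lat": ("along_km", [s.lat for s in stations]),
                "station_lon": ("along_km", [s.lon for s in stations])})
    return ds


def refine_along_track(section: xr.Dataset, step_km: float) -> xr.Dataset:
    """Resample a gridded section onto a finer along-track axis (linear)."""
    along = section["along_km"].values
    fine = np.arange(along[0], along[-1] + step_km / 2, step_km)
    vals = section["delta3he"].values
    out = np.full((vals.shape[0], fine.size), np.nan)
    for k in range(vals.shape[0]):
        ok = np.isfinite(vals[k])
        if ok.sum() < 2:
            continue
        seg = (fine >= along[ok].min()) & (fine <= along[ok].max())
        out[k, seg] = np.interp(fine[seg], along[ok], vals[k][ok])
    return xr.Dataset(
        {"delta3he": (("depth", "along_km"), out, {"units": "percent"})},
        coords={"depth": section["depth"].values, "along_km": fine})


def flag_high_eke(stations: Sequence[TracerStation], eke_field: xr.DataArray,
                  threshold: float = 150.0) -> np.ndarray:
    """Per-station flag: surface EKE at the nearest fine-grid node is
    strictly above ``threshold`` (cm^2 s^-2).  Stations outside the EKE
    field are unflagged with a warning."""
    lats = eke_field["lat"].values
    lons = eke_field["lon"].values
    flags = np.zeros(len(stations), dtype=bool)
    for k, st in enumerate(stations):
        if not (lats.min() <= st.lat <= lats.max()
                and lons.min() <= st.lon <= lons.max()):
            warnings.warn(f"station {st.station} outside EKE field: unflagged")
            continue
        j = int(np.argmin(np.abs(lats - st.lat)))
        i = int(np.argmin(np.abs(lons - st.lon)))
        val = float(np.asarray(eke_field.values)[j, i])
        flags[k] = np.isfinite(val) and val > threshold
    return flags
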