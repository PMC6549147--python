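"""Gridded potential-density climatology and alongstream isopycnal diagnosis.

Heterogeneous hydrographic profiles (ship CTD, floats, animal-borne sensors;
quality flag 1 only) are interpolated to standard pressure levels (25 dbar
spacing, 0-2000 dbar), converted to potential density sigma-0, and mapped
per level onto a regular grid by an isotropic Gaussian-weighted optimal
interpolation (decorrelation scale 550 km by default).

Two meridional sections are then extracted and compared *alongstream* by
resampling each from latitude to dynamic-height (dh) coordinate: because ACC
fronts and jets follow dh contours, differencing at fixed dh compares the
same streamline upstream and downstream, so a pure meridional meander of the
front produces no signal while a genuine alongstream change in the density
structure (isopycnal shoaling) does.  The dh axis is finally relabelled as a
pseudo-latitude through the sector-mean dh(lat) relation.

The sign convention is Delta-sigma = sigma(downstream) - sigma(upstream);
positive values at depth mean denser water at fixed pressure downstream,
i.e. isopycnals shallower downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import xarray as xr

from .eke import great_circle_km
from .profiles import potential_density

log = logging.getLogger("ventbloom")


@dataclass
class HydroProfile:
    """One hydrographic cast (any platform) entering the climatology."""

    profile_id: str
    source: str            # ship | float | animal
    qc_flag: int
    time: pd.Timestamp
    lat: float
    lon: float
    pres: np.ndarray       # dbar, strictly increasing
    temp: np.ndarray       # deg C
    psal: np.ndarray

    def __post_init__(self):
        self.pres = np.asarray(self.pres, dtype=float)
        self.temp = np.asarray(self.temp, dtype=float)
        self.psal = np.asarray(self.psal, dtype=float)


def hydro_from_frame(df: pd.DataFrame) -> list:
    """Group a one-row-per-level hydrography table into HydroProfile objects."""
    out = []
    for pid, g in df.groupby("profile_id", sort=False):
        g = g.sort_values("pres_dbar")
        out.append(HydroProfile(
            profile_id=str(pid), source=str(g["source"].iloc[0]),
            qc_flag=int(g["qc_flag"].iloc[0]),
            time=pd.Timestamp(g["time"].iloc[0]),
            lat=float(g["lat"].iloc[0]), lon=float(g["lon"].iloc[0]),
            pres=g["pres_dbar"].to_numpy(), temp=g["temp_C"].to_numpy(),
            psal=g["psal"].to_numpy()))
    return out


def standard_levels(dz: float = 25.0, p_max: float = 2000.0) -> np.ndarray:
    """Standard pressure levels 0, dz, ..., p_max dbar."""
    return np.arange(0.0, p_max + dz / 2, dz)


def bin_profiles_vertical(profiles: Sequence[HydroProfile],
                          levels: Optional[np.ndarray] = None):
    """Per-profile sigma-0 at standard levels.

    T and S are linearly interpolated to each level's pressure; levels
    outside the sampled range stay missing (no extrapolation).  Profiles
    with a quality flag other than 1 or spanning fewer than two standard
    levels are dropped and logged.  Returns (lon, lat, sigma[n, n_levels]).
    """
    if levels is None:
        levels = standard_levels()
    lons, lats, rows = [], [], []
    n_drop = 0
    for p in profiles:
        if p.qc_flag != 1:
            n_drop += 1
            continue
        ok = np.isfinite(p.pres) & np.isfinite(p.temp) & np.isfinite(p.psal)
        pres, temp, psal = p.pres[ok], p.temp[ok], p.psal[ok]
        if pres.size < 2:
            n_drop += 1
            continue
        inside = (levels >= pres[0]) & (levels <= pres[-1])
        if inside.sum() < 2:
            n_drop += 1
            continue
        t_lev = np.where(inside, np.interp(levels, pres, temp), np.nan)
        s_lev = np.where(inside, np.interp(levels, pres, psal), np.nan)
        sig = potential_density(t_lev, s_lev, levels, p.lat, p.lon)
        lons.append(p.lon)
        lats.append(p.lat)
        rows.append(sig)
    if n_drop:
        log.info("dropped %d profiles (QC flag or <2 standard levels)", n_drop)
    if not rows:
        return np.empty(0), np.empty(0), np.empty((0, levels.size))
    return np.asarray(lons), np.asarray(lats), np.vstack(rows)


def optimal_interpolation(lons, lats, sigma, grid_lon, grid_lat,
                          levels=None, scale_km: float = 550.0,
                          n_eff_floor: float = 0.2) -> xr.Dataset:
    """Isotropic-Gaussian optimal interpolation of level samples onto a grid.

    Node value per level = normalised Gaussian-weighted mean of the samples
    (weights exp(-d^2 / 2 L^2)); n_eff = sum of weights.  Nodes with
    n_eff < ``n_eff_floor`` are missing.  The final field is vertically
    sorted at each node (convective adjustment of the climatology) and the
    number of sorted nodes is recorded in the attributes.
    """
    if levels is None:
        levels = standard_levels()
    sigma = np.asarray(sigma, dtype=float)
    if sigma.shape != (np.size(lons), np.size(levels)):
        raise ValueError("sigma must have shape (n_samples, n_levels)")
    glat, glon = np.meshgrid(grid_lat, grid_lon, indexing="ij")
    if sigma.shape[0] == 0:
        warnings.warn("no samples: climatology is all-missing")
        shape = (np.size(levels), np.size(grid_lat), np.size(grid_lon))
        return _clim_dataset(np.full(shape, np.nan), np.zeros(shape[1:]),
                             levels, grid_lat, grid_lon, 0)
    d = great_circle_km(glon[..., None], glat[..., None],
                        np.asarray(lons), np.asarray(lats))
    w = np.exp(-d ** 2 / (2.0 * scale_km ** 2))          # (nlat, nlon, nsamp)
    out = np.full((np.size(levels), np.size(grid_lat), np.size(grid_lon)), np.nan)
    n_eff = np.zeros((np.size(grid_lat), np.size(grid_lon)))
    for k in range(np.size(levels)):
        vals = sigma[:, k]
        ok = np.isfinite(vals)
        if not ok.any():
            continue
        wk = w[..., ok]
        wsum = wk.sum(axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            fld = (wk * vals[ok]).sum(axis=-1) / wsum
        out[k] = np.where(wsum >= n_eff_floor, fld, np.nan)
        n_eff = np.maximum(n_eff, wsum)
    # stable stratification: sort finite values of each vertical column in
    # place (convective adjustment), preserving the missing pattern
    n_sorted = 0
    for j in range(out.shape[1]):
        for i in range(out.shape[2]):
            col = out[:, j, i]
            fin = np.isfinite(col)
            if fin.sum() < 2:
                continue
            vals = col[fin]
            if np.any(np.diff(vals) < 0):
                n_sorted += 1
                col[fin] = np.sort(vals)
    return _clim_dataset(out, n_eff, levels, grid_lat, grid_lon, n_sorted)


def _clim_dataset(sigma, n_eff, levels, grid_lat, grid_lon, n_sorted):
    ds = xr.Dataset(
        {"sigma": (("pressure", "lat", "lon"), sigma, {"units": "kg m-3"}),
         "n_eff": (("lat", "lon"), n_eff)},
        coords={"pressure": ("pressure", np.asarray(levels), {"units": "dbar"}),
                "lat": np.asarray(grid_lat), "lon": np.asarray(grid_lon)})
    ds.attrs["n_nodes_convectively_sorted"] = n_sorted
    return ds


def extract_section(clim: xr.Dataset, lon: float,
                    lat_range: Tuple[float, float] = (-55.0, -47.0)) -> xr.DataArray:
    """Meridional section sigma(P, lat) at ``lon`` by bilinear sampling."""
    glon = clim["lon"].values
    if not (glon.min() <= lon <= glon.max()):
        raise ValueError(f"section longitude {lon} outside grid "
                         f"[{glon.min()}, {glon.max()}]")
    sec = clim["sigma"].interp(lon=lon, method="linear")
    lo, hi = min(lat_range), max(lat_range)
    sec = sec.sel(lat=slice(lo, hi))
    sec.attrs["section_lon"] = lon
    return sec


def _monotone_envelope(x):
    """Boolean mask of the largest prefix-monotone run (increasing or
    decreasing) of x; interior reversals are excluded."""
    x = np.asarray(x, dtype=float)
    d = np.diff(x)
    increasing = np.nansum(d > 0) >= np.nansum(d < 0)
    keep = np.ones(x.size, dtype=bool)
    best = x[0]
    for i in range(1, x.size):
        ok = x[i] > best if increasing else x[i] < best
        if ok:
            best = x[i]
        else:
            keep[i] = False
    return keep


def to_dh_coordinate(section: xr.DataArray, dh_along: np.ndarray,
                     dh_axis: Optional[np.ndarray] = None) -> xr.DataArray:
    """Resample sigma(P, lat) to sigma(P, dh) by linear interpolation.

    ``dh_along`` gives dynamic height at the section's latitudes.  Where
    dh(lat) is non-monotone the largest monotone envelope is used and the
    excluded latitudes are flagged in the attributes.
    """
    lat = section["lat"].values
    dh_along = np.asarray(dh_along, dtype=float)
    if dh_along.size != lat.size:
        raise ValueError("dh_along must match the section latitude axis")
    keep = _monotone_envelope(dh_along)
    excluded = lat[~keep]
    dh_mono = dh_along[keep]
    vals = section.values[:, keep]
    order = np.argsort(dh_mono)
    dh_mono = dh_mono[order]
    vals = vals[:, order]
    if dh_axis is None:
        dh_axis = np.linspace(dh_mono[0], dh_mono[-1], dh_mono.size)
    out = np.full((section.shape[0], np.size(dh_axis)), np.nan)
    inside = (dh_axis >= dh_mono[0]) & (dh_axis <= dh_mono[-1])
    for k in range(section.shape[0]):
        col = vals[k]
        ok = np.isfinite(col)
        if ok.sum() < 2:
            continue
        out[k, inside] = np.interp(dh_axis[inside], dh_mono[ok], col[ok])
    da = xr.DataArray(out, coords={"pressure": section["pressure"].values,
                                   "dh": np.asarray(dh_axis)},
                      dims=("pressure", "dh"), name="sigma")
    da.attrs["excluded_lats"] = list(map(float, excluded))
    if "section_lon" in section.attrs:
        da.attrs["section_lon"] = section.attrs["section_lon"]
    return da


@dataclass
class AlongstreamDifference:
    """Alongstream density contrast between two meridional sections."""

    delta_sigma_dh: xr.DataArray       # (pressure, dh), downstream - upstream
    delta_sigma_pseudolat: xr.DataArray  # (pressure, pseudo_lat)
    pseudo_lat: np.ndarray             # degrees, monotone image of the dh axis
    flags: Tuple[str, ...] = ()


def _isotonic_decreasing(y):
    """Pool-adjacent-violators fit of a non-increasing sequence."""
    y = np.asarray(y, dtype=float).copy()
    n = y.size
    vals = list(y)
    wts = [1.0] * n
    i = 0
    while i < len(vals) - 1:
        if vals[i] < vals[i + 1] - 1e-12:
            merged = (vals[i] * wts[i] + vals[i + 1] * wts[i + 1]) / (wts[i] + wts[i + 1])
            vals[i] = merged
            wts[i] += wts[i + 1]
            del vals[i + 1], wts[i + 1]
            i = max(i - 1, 0)
        else:
            i += 1
    out = np.concatenate([[v] * int(w) for v, w in zip(vals, wts)])
    return out


def alongstream_delta_sigma(sec_down: xr.DataArray, sec_up: xr.DataArray,
                            sector_lat: np.ndarray, sector_dh: np.ndarray
                            ) -> AlongstreamDifference:
    """Delta-sigma(P, dh) = sigma_downstream - sigma_upstream, plus the
    pseudo-latitude relabelling via the sector-mean dh(lat).

    Both sections must already be on dh coordinate (``to_dh_coordinate``)
    with overlapping dh ranges.  The pseudo-latitude map inverts the
    sector-mean dh(lat); if that relation is non-monotone an isotonic
    (monotone) regression is applied first and flagged.
    """
    flags = []
    dh_d = sec_down["dh"].values
    dh_u = sec_up["dh"].values
    lo = max(dh_d.min(), dh_u.min())
    hi = min(dh_d.max(), dh_u.max())
    if not lo < hi:
        raise ValueError("empty dynamic-height overlap between sections")
    dh_axis = np.linspace(lo, hi, max(dh_d.size, dh_u.size))
    a = _interp_columns(sec_down, dh_axis)
    b = _interp_columns(sec_up, dh_axis)
    delta = a - b
    d_dh = xr.DataArray(delta, coords={"pressure": sec_down["pressure"].values,
                                       "dh": dh_axis},
                        dims=("pressure", "dh"), name="delta_sigma",
                        attrs={"units": "kg m-3",
                               "convention": "downstream minus upstream"})

    # pseudo-latitude: invert sector-mean dh(lat)
    sector_lat = np.asarray(sector_lat, dtype=float)
    sector_dh = np.asarray(sector_dh, dtype=float)
    order = np.argsort(sector_lat)
    slat, sdh = sector_lat[order], sector_dh[order]
    d = np.diff(sdh)
    if np.any(d > 0) and np.any(d < 0):
        flags.append("sector_dh_nonmonotone_isotonic_applied")
        if np.nansum(d < 0) >= np.nansum(d > 0):
            sdh = _isotonic_decreasing(sdh)
        else:
            sdh = -_isotonic_decreasing(-sdh)
    if sdh[0] > sdh[-1]:
        slat_i, sdh_i = slat[::-1], sdh[::-1]
    else:
        slat_i, sdh_i = slat, sdh
    sdh_i, uniq = np.unique(sdh_i, return_index=True)
    pseudo_lat = np.interp(dh_axis, sdh_i, slat_i[uniq])
    d_pl = xr.DataArray(delta, coords={"pressure": sec_down["pressure"].values,
                                       "pseudo_lat": ("dh", pseudo_lat),
                                       "dh": dh_axis},
                        dims=("pressure", "dh"), name="delta_sigma",
                        attrs=d_dh.attrs)
    return AlongstreamDifference(delta_sigma_dh=d_dh, delta_sigma_pseudolat=d_pl,
                                 pseudo_lat=pseudo_lat, flags=tuple(flags))


def _interp_columns(sec: xr.DataArray, dh_axis: np.ndarray) -> np.ndarray:
    dh = sec["dh"].values
    vals = sec.values
    out = np.full((vals.shape[0], dh_axis.size), np.nan)
    for k in range(vals.shape[0]):
        ok = np.isfinite(vals[k])
        if ok.sum() < 2:
            continue
        inside = (dh_axis >= dh[ok].min()) & (dh_axis <= dh[ok].max())
        out[k, inside] = np.interp(dh_axis[inside], dh[ok], vals[k][ok])
    return out
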