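"""Gridded velocity time series.

Carrier for altimetry-style surface geostrophic velocities u, v on a regular
lon/lat grid with a strictly increasing time axis.  Velocities are stored in
m s^-1; land/missing cells are NaN.  Provides the space-time linear
interpolation used by the Lagrangian advection scheme: bilinear in space,
linear in time, with missing neighbours dropped from the bilinear stencil by
weight renormalisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_EPOCH = np.datetime64("2000-01-01T00:00:00", "s")


def to_hours(times):
    """Convert datetime-like (scalar or array) to float hours since 2000-01-01."""
    scalar = np.ndim(times) == 0 and not isinstance(times, (list, tuple))
    idx = pd.to_datetime(np.ravel(np.asarray(times, dtype=object)))
    t = idx.values.astype("datetime64[s]")
    out = (t - _EPOCH).astype(float) / 3600.0
    return float(out[0]) if scalar else out


def from_hours(hours) -> np.ndarray:
    """Inverse of :func:`to_hours`."""
    h = np.asarray(hours, dtype=float)
    return _EPOCH + (h * 3600.0).round().astype("timedelta64[s]")


class FieldError(ValueError):
    """Grid violates a structural requirement."""


@dataclass
class VelocityFieldSeries:
    """u, v (time, lat, lon) on a regular grid; SI units (m s^-1)."""

    time_h: np.ndarray   # hours since 2000-01-01, strictly increasing
    lat: np.ndarray      # degrees, regular, increasing
    lon: np.ndarray      # degrees in [0, 360), regular, increasing
    u: np.ndarray        # (time, lat, lon) m s^-1, NaN = land/missing
    v: np.ndarray

    def __post_init__(self):
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.time_h.size > 1 and not np.all(np.diff(self.time_h) > 0):
            raise FieldError("time axis must be strictly increasing")
        for name, ax in (("lat", self.lat), ("lon", self.lon)):
            if ax.size < 2:
                raise FieldError(f"{name} axis needs >= 2 nodes")
            steps = np.diff(ax)
            if not np.all(steps > 0) or not np.allclose(steps, steps[0], rtol=1e-6):
                raise FieldError(f"{name} axis must be regular and increasing")
        shape = (self.time_h.size, self.lat.size, self.lon.size)
        if self.u.shape != shape or self.v.shape != shape:
            raise FieldError(f"u/v must have shape {shape}")
        # cached scalars for the fast interpolation path
        self._lat0 = float(self.lat[0]); self._dlat = float(self.lat[1] - self.lat[0])
        self._lon0 = float(self.lon[0]); self._dlon = float(self.lon[1] - self.lon[0])

    @property
    def times(self) -> np.ndarray:
        return from_hours(self.time_h)

    def time_slab(self, t_h: float):
        """Indices (k0, k1) and weight w of time interpolation at t_h.

        A single-slice series is constant in time.  Raises FieldError when
        t_h lies outside the series span.
        """
        th = self.time_h
        if th.size == 1:
            return 0, 0, 0.0
        if t_h < th[0] - 1e-9 or t_h > th[-1] + 1e-9:
            raise FieldError(f"time {t_h} h outside series span [{th[0]}, {th[-1]}]")
        k1 = int(np.searchsorted(th, t_h))
        if k1 == 0:
            return 0, 0, 0.0
        if k1 >= th.size:
            return th.size - 1, th.size - 1, 0.0
        k0 = k1 - 1
        w = (t_h - th[k0]) / (th[k1] - th[k0])
        return k0, k1, float(w)

    def interp(self, lon: float, lat: float, t_h: float):
        """(u, v) at a point: bilinear in space, linear in time.

        Missing spatial neighbours get zero weight with renormalisation; if
        all four neighbours are missing the velocity is undefined and
        (nan, nan) is returned.
        """
        fx = (lon - self._lon0) / self._dlon
        fy = (lat - self._lat0) / self._dlat
        i0 = int(np.floor(fx)); j0 = int(np.floor(fy))
        if i0 < 0 or j0 < 0 or i0 + 1 >= self.lon.size or j0 + 1 >= self.lat.size:
            return float("nan"), float("nan")
        ax = fx - i0
        ay = fy - j0
        k0, k1, wt = self.time_slab(t_h)

        wts = ((1 - ax) * (1 - ay), ax * (1 - ay), (1 - ax) * ay, ax * ay)
        idx = ((j0, i0), (j0, i0 + 1), (j0 + 1, i0), (j0 + 1, i0 + 1))
        out = []
        for comp in (self.u, self.v):
            num = 0.0
            den = 0.0
            for w, (j, i) in zip(wts, idx):
                a = comp[k0, j, i]
                b = comp[k1, j, i]
                val = a if k0 == k1 else (1 - wt) * a + wt * b
                if np.isfinite(val):
                    num += w * val
                    den += w
            out.append(num / den if den > 0 else float("nan"))
        return out[0], out[1]

    def covers(self, lon: float, lat: float) -> bool:
        return (self.lon[0] <= lon <= self.lon[-1]
                and self.lat[0] <= lat <= self.lat[-1])
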