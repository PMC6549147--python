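"""Pipeline configuration.

A single flat configuration object carries every tunable constant of the
pipeline: the fluorometer calibration (dark counts, slope, and the Southern
Ocean correction factor F490), the mixed-layer criterion, the bloom phenology
windows, the eddy-kinetic-energy binning/smoothing settings, the optimal
interpolation scale of the density climatology, and the Lagrangian advection
parameters (RK4 step, scavenging e-folding time, lookback horizon, source
disks).  Config files are a flat ``key = value`` text format; every run logs
the fully resolved configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Tuple


class ConfigError(ValueError):
    """Invalid configuration value or file."""


@dataclass
class CalibrationSpec:
    """Fluorescence-to-chlorophyll calibration.

    chl = max(counts - dark, 0) * slope * f490.  ``f490`` is the Southern
    Ocean radiometric correction to the factory calibration; the adopted
    conservative value 0.3 implies a factory overestimation factor of
    1/0.3 ~ 3.3.
    """

    dark: float = 47.0          # counts
    slope: float = 0.012        # mg m^-3 per count
    f490: float = 0.3           # dimensionless, in (0, 1]

    def validate(self) -> None:
        if not self.slope > 0:
            raise ConfigError("calibration slope must be > 0")
        if not (0.0 < self.f490 <= 1.0):
            raise ConfigError("f490 must lie in (0, 1]")


@dataclass
class PipelineConfig:
    calibration: CalibrationSpec = field(default_factory=CalibrationSpec)

    # mixed layer
    mld_threshold: float = 0.03     # kg m^-3 density increase over reference
    mld_ref_depth: float = 10.0     # m (1 dbar ~ 1 m convention)

    # bloom phenology
    bloom_window_start: str = "11-01"   # month-day, inclusive
    bloom_window_end: str = "02-28"     # month-day (29 Feb included in leap years)
    cycle_start: str = "07-01"          # annual cycle anchor
    bin_days: int = 20
    min_profiles: int = 8

    # eddy kinetic energy
    eke_bin_deg: float = 1.0
    eke_min_count: int = 5          # strictly more than this many samples kept
    eke_radius_km: float = 100.0    # Gaussian decorrelation radius for smoothing
    high_eke_threshold: float = 150.0   # cm^2 s^-2, tracer-station highlighting

    # density climatology
    oi_scale_km: float = 550.0      # isotropic Gaussian decorrelation scale
    dz_m: float = 25.0              # vertical level spacing, 0-2000 m
    grid_res_deg: float = 0.5
    n_eff_floor: float = 0.2        # minimum effective data count per node

    # Lagrangian iron delivery
    rk4_dt_h: float = 6.0
    scavenging_efold_days: float = 90.0
    lookback_days: float = 150.0
    seed_resolution_deg: float = 0.25
    # (lon_deg, lat_deg, radius_deg) disks marking the upwelled ridge source
    source_disks: Tuple[Tuple[float, float, float], ...] = (
        (30.0, -50.0, 1.0),
        (30.5, -49.5, 1.0),
    )
    shallow_source_max_depth: float = 500.0   # m, shallow-bathymetry iron source

    # euphotic depth: log10(Zeu) = c0 + c1*x + c2*x^2 + c3*x^3, x = log10(Chl_surf)
    zeu_coeffs: Tuple[float, float, float, float] = (1.524, -0.436, -0.0145, 0.0186)
    surface_layer_m: float = 10.0   # "surface" Chl = mean over this top layer

    earth_radius_km: float = 6371.0
    rng_seed: int = 0

    def validate(self) -> None:
        self.calibration.validate()
        positive = {
            "mld_threshold": self.mld_threshold,
            "mld_ref_depth": self.mld_ref_depth,
            "bin_days": self.bin_days,
            "eke_bin_deg": self.eke_bin_deg,
            "eke_radius_km": self.eke_radius_km,
            "oi_scale_km": self.oi_scale_km,
            "dz_m": self.dz_m,
            "grid_res_deg": self.grid_res_deg,
            "rk4_dt_h": self.rk4_dt_h,
            "scavenging_efold_days": self.scavenging_efold_days,
            "lookback_days": self.lookback_days,
            "seed_resolution_deg": self.seed_resolution_deg,
            "shallow_source_max_depth": self.shallow_source_max_depth,
            "earth_radius_km": self.earth_radius_km,
            "surface_layer_m": self.surface_layer_m,
        }
        for name, val in positive.items():
            if not val > 0:
                raise ConfigError(f"{name} must be strictly positive, got {val}")
        if self.min_profiles < 1:
            raise ConfigError("min_profiles must be >= 1")
        if self.eke_min_count < 0:
            raise ConfigError("eke_min_count must be >= 0")
        for md in (self.bloom_window_start, self.bloom_window_end, self.cycle_start):
            _parse_month_day(md)
        for disk in self.source_disks:
            if len(disk) != 3 or not disk[2] > 0:
                raise ConfigError(f"source disk must be (lon, lat, radius>0): {disk}")

    # -- flat key=value serialisation ------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        cal = d.pop("calibration")
        d.update({f"cal_{k}": v for k, v in cal.items()})
        d["source_disks"] = json.dumps([list(x) for x in self.source_disks])
        d["zeu_coeffs"] = json.dumps(list(self.zeu_coeffs))
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        cal_kwargs = {}
        for k in ("dark", "slope", "f490"):
            if f"cal_{k}" in d:
                cal_kwargs[k] = float(d.pop(f"cal_{k}"))
        kwargs = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for key, raw in d.items():
            if key not in fields:
                raise ConfigError(f"unknown configuration key: {key}")
            if key == "source_disks":
                kwargs[key] = tuple(tuple(float(v) for v in x)
                                    for x in json.loads(raw) if len(x) == 3) \
                    if isinstance(raw, str) else tuple(map(tuple, raw))
            elif key == "zeu_coeffs":
                vals = json.loads(raw) if isinstance(raw, str) else raw
                kwargs[key] = tuple(float(v) for v in vals)
            else:
                typ = fields[key].type
                if typ == "int":
                    kwargs[key] = int(raw)
                elif typ == "float":
                    kwargs[key] = float(raw)
                else:
                    kwargs[key] = str(raw)
        cfg = cls(calibration=CalibrationSpec(**cal_kwargs), **kwargs)
        cfg.validate()
        return cfg

    def write(self, path) -> None:
        lines = [f"{k} = {v}" for k, v in self.to_dict().items()]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read(cls, path) -> "PipelineConfig":
        d = {}
        for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{i}: expected 'key = value', got {line!r}")
            key, _, value = line.partition("=")
            d[key.strip()] = value.strip()
        return cls.from_dict(d)

    def config_hash(self) -> str:
        """Stable hash of the fully resolved configuration, for run logs."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _parse_month_day(md: str) -> Tuple[int, int]:
    try:
        month, day = md.split("-")
        month, day = int(month), int(day)
    except Exception as exc:
        raise ConfigError(f"bad month-day value {md!r}") from exc
    if not (1 <= month <= 12 and 1 <= day <= 31):
        raise ConfigError(f"bad month-day value {md!r}")
    return month, day


def month_day(md: str) -> Tuple[int, int]:
    """Parse a validated 'MM-DD' string into (month, day)."""
    return _parse_month_day(md)
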