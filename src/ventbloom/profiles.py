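"""BGC-Argo profile processing.

Turns a raw float cast (pressure, temperature, salinity, chlorophyll
fluorescence counts, backscattering) into a calibrated chlorophyll profile
with mixed layer depth (MLD), euphotic depth (Zeu) and depth-integrated
biomass.  The processing chain follows standard BGC-Argo practice:

1. potential density (sigma-0) from T/S/P;
2. MLD as the shallowest depth where sigma-0 exceeds its 10 m reference by
   0.03 kg m^-3, located by linear interpolation between bracketing levels;
3. non-photochemical quenching (NPQ) correction on daytime profiles: the
   maximum fluorescence at or above the MLD is extrapolated to the surface;
4. calibration chl = max(counts - dark, 0) * slope * F490;
5. euphotic depth from surface chlorophyll via a log-log cubic;
6. trapezoidal integration of chlorophyll from the surface down to
   max(MLD, Zeu).

The NPQ correction is applied to raw fluorescence before calibration; since
the calibration is affine with a clamp at the dark value, the two orders
agree whenever counts exceed dark.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import CalibrationSpec, PipelineConfig
from . import seawater


class ProfileError(ValueError):
    """Profile violates a structural invariant or a precondition."""


@dataclass
class FloatProfile:
    """One vertical cast from a profiling float.

    Arrays are aligned level-by-level with strictly increasing pressure.
    ``day_flag`` is True for daytime casts (subject to quenching).
    """

    float_id: str
    cycle: int
    time: pd.Timestamp
    lat: float
    lon: float
    day_flag: bool
    pres: np.ndarray      # dbar
    temp: np.ndarray      # deg C
    psal: np.ndarray      # practical salinity
    fluo: np.ndarray      # counts
    bbp700: np.ndarray    # m^-1

    def __post_init__(self):
        for name in ("pres", "temp", "psal", "fluo", "bbp700"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.pres.size
        for name in ("temp", "psal", "fluo", "bbp700"):
            if getattr(self, name).size != n:
                raise ProfileError(
                    f"{self.float_id} cycle {self.cycle}: {name} length "
                    f"{getattr(self, name).size} != pres length {n}")
        if n >= 2 and not np.all(np.diff(self.pres) > 0):
            raise ProfileError(
                f"{self.float_id} cycle {self.cycle}: pressure not strictly increasing")
        self.time = pd.Timestamp(self.time)

    @property
    def n_levels(self) -> int:
        return self.pres.size


@dataclass
class ProcessedProfile:
    """Calibrated chlorophyll profile with derived bloom quantities."""

    parent: FloatProfile
    chl: np.ndarray                 # mg m^-3, aligned with parent.pres
    mld: float                      # m
    zeu: float                      # m
    integrated_chl: float           # mg m^-2
    integration_depth: float        # m = max(mld, zeu)
    flags: Tuple[str, ...] = ()


def potential_density(temp, psal, pres, lat=None, lon=None):
    """Potential density anomaly sigma-0 (kg m^-3) referenced to the surface.

    ``lat``/``lon`` are accepted for interface symmetry with position-aware
    equations of state; the EOS-80 formulation used here does not need them.
    Out-of-range inputs (T outside [-2.5, 40] degC, S outside [2, 42]) are
    returned as NaN, to be dropped by level QC.
    """
    T = np.asarray(temp, dtype=float)
    S = np.asarray(psal, dtype=float)
    P = np.asarray(pres, dtype=float)
    ok = (T >= -2.5) & (T <= 40.0) & (S >= 2.0) & (S <= 42.0)
    out = np.where(ok, seawater.sigma0(np.where(ok, S, 35.0),
                                       np.where(ok, T, 10.0),
                                       np.where(ok, P, 0.0)), np.nan)
    return out


def mld_from_density(depth, sigma0, threshold=0.03, ref_depth=10.0):
    """Mixed layer depth from a sigma-0 profile by threshold crossing.

    Returns ``(mld_m, flag)``.  The reference density is sigma-0 linearly
    interpolated to ``ref_depth``; if the shallowest level lies within
    [ref_depth, ref_depth + 5 m] it is used directly with flag
    ``"mld_ref_approx"``; deeper still, the MLD is undefined (NaN, flag
    ``"mld_undefined"``).  The MLD is the shallowest depth where sigma-0
    exceeds reference + threshold, linearly interpolated between the
    bracketing levels; if the threshold is never exceeded, the deepest
    sampled depth is returned with flag ``"mld_never_exceeded"``.
    """
    z = np.asarray(depth, dtype=float)
    s = np.asarray(sigma0, dtype=float)
    keep = np.isfinite(z) & np.isfinite(s)
    z, s = z[keep], s[keep]
    if z.size < 2:
        return float("nan"), "mld_undefined"

    flag = ""
    if z[0] <= ref_depth:
        s_ref = float(np.interp(ref_depth, z, s))
    elif z[0] <= ref_depth + 5.0:
        s_ref = float(s[0])
        flag = "mld_ref_approx"
    else:
        return float("nan"), "mld_undefined"

    target = s_ref + threshold
    below = np.nonzero((s > target) & (z > ref_depth))[0]
    if below.size == 0:
        return float(z[-1]), (flag + "+" if flag else "") + "mld_never_exceeded"
    j = below[0]
    if j == 0:
        return float(z[0]), flag or "mld_surface"
    z0, z1 = z[j - 1], z[j]
    s0, s1 = s[j - 1], s[j]
    if s1 == s0:
        mld = float(z1)
    else:
        mld = float(z0 + (target - s0) / (s1 - s0) * (z1 - z0))
    return max(mld, ref_depth), flag


def compute_mld(profile: FloatProfile, threshold=0.03, ref_depth=10.0):
    """MLD (m) of a float profile; see :func:`mld_from_density`.

    Pressure in dbar is treated as depth in m (the customary near-surface
    convention; recorded in output metadata).
    """
    sig = potential_density(profile.temp, profile.psal, profile.pres,
                            profile.lat, profile.lon)
    return mld_from_density(profile.pres, sig, threshold, ref_depth)


def npq_correct(profile: FloatProfile, mld: float) -> np.ndarray:
    """Non-photochemical-quenching correction of raw fluorescence.

    Daytime casts only: the maximum fluorescence at or above the MLD is
    extrapolated toward the surface (every shallower value is replaced by
    it).  Night casts are returned unchanged.  If no levels lie at or above
    the MLD the cast is returned unchanged (no-op).
    """
    fluo = profile.fluo.copy()
    if not profile.day_flag or not np.isfinite(mld):
        return fluo
    above = profile.pres <= mld
    if not above.any():
        return fluo
    idx_above = np.nonzero(above)[0]
    finite = idx_above[np.isfinite(fluo[idx_above])]
    if finite.size == 0:
        return fluo
    j = finite[np.argmax(fluo[finite])]
    fluo[: j] = fluo[j]
    return fluo


def calibrate_chl(fluo, cal: CalibrationSpec) -> np.ndarray:
    """Counts -> chlorophyll (mg m^-3): max(counts - dark, 0) * slope * f490."""
    cal.validate()
    f = np.asarray(fluo, dtype=float)
    return np.clip(f - cal.dark, 0.0, None) * cal.slope * cal.f490


def euphotic_depth(chl_surface: float,
                   coeffs: Sequence[float] = (1.524, -0.436, -0.0145, 0.0186)) -> float:
    """Euphotic depth (m): depth of 1% surface irradiance from surface Chl.

    Log-log cubic in surface chlorophyll,
    log10(Zeu) = c0 + c1 x + c2 x^2 + c3 x^3 with x = log10(Chl_surf);
    monotonically non-increasing in chlorophyll over the oceanic range
    (clearer water -> deeper euphotic layer).
    """
    if not chl_surface > 0:
        raise ValueError(f"surface chlorophyll must be > 0, got {chl_surface}")
    x = math.log10(chl_surface)
    c0, c1, c2, c3 = coeffs
    return 10.0 ** (c0 + x * (c1 + x * (c2 + x * c3)))


def integrate_chl(chl, depths, z_max: float) -> float:
    """Trapezoidal integral of chlorophyll (mg m^-2) from 0 to ``z_max`` m.

    The shallowest value is extended to the surface; the value at ``z_max``
    is obtained by linear interpolation.  Raises :class:`ProfileError` when
    no finite level lies above ``z_max``.
    """
    if not z_max > 0:
        raise ValueError(f"z_max must be > 0, got {z_max}")
    c = np.asarray(chl, dtype=float)
    z = np.asarray(depths, dtype=float)
    keep = np.isfinite(c) & np.isfinite(z)
    c, z = c[keep], z[keep]
    if c.size == 0 or not (z <= z_max).any():
        raise ProfileError("no finite chlorophyll levels above integration depth")
    # surface extension
    if z[0] > 0:
        z = np.concatenate([[0.0], z])
        c = np.concatenate([[c[0]], c])
    if z[-1] < z_max:
        zz, cc = z, c  # integrate to the deepest sample (no extrapolation)
        z_stop = z[-1]
    else:
        c_at = float(np.interp(z_max, z, c))
        inside = z < z_max
        zz = np.concatenate([z[inside], [z_max]])
        cc = np.concatenate([c[inside], [c_at]])
        z_stop = z_max
    del z_stop
    return float(np.trapezoid(cc, zz))


def process_profile(profile: FloatProfile, cfg: Optional[PipelineConfig] = None
                    ) -> ProcessedProfile:
    """Full processing chain for one cast: MLD, NPQ, calibration, Zeu, integral."""
    cfg = cfg or PipelineConfig()
    flags = []
    mld, mld_flag = compute_mld(profile, cfg.mld_threshold, cfg.mld_ref_depth)
    if mld_flag:
        flags.append(mld_flag)
    fluo = npq_correct(profile, mld)
    chl = calibrate_chl(fluo, cfg.calibration)

    top = profile.pres <= cfg.surface_layer_m
    if top.any() and np.isfinite(chl[top]).any():
        chl_surf = float(np.nanmean(chl[top]))
    else:
        chl_surf = float(chl[np.isfinite(chl)][0]) if np.isfinite(chl).any() else np.nan
        flags.append("surface_chl_from_shallowest")
    if not chl_surf > 0:
        chl_surf = 1e-3  # oligotrophic floor so Zeu stays defined
        flags.append("surface_chl_floor")
    zeu = euphotic_depth(chl_surf, cfg.zeu_coeffs)

    z_int = max(mld, zeu) if np.isfinite(mld) else zeu
    try:
        ichl = integrate_chl(chl, profile.pres, z_int)
    except ProfileError:
        ichl = float("nan")
        flags.append("integration_failed")
    return ProcessedProfile(parent=profile, chl=chl, mld=mld, zeu=zeu,
                            integrated_chl=ichl, integration_depth=z_int,
                            flags=tuple(flags))


def process_series(profiles, cfg: Optional[PipelineConfig] = None):
    """Process a time-sorted sequence of casts; returns list of ProcessedProfile."""
    cfg = cfg or PipelineConfig()
    return [process_profile(p, cfg) for p in profiles]


def processed_to_frame(processed) -> pd.DataFrame:
    """Tabulate processed profiles (one row per cast)."""
    rows = []
    for pp in processed:
        p = pp.parent
        rows.append({
            "float_id": p.float_id, "cycle": p.cycle, "time": p.time,
            "lat": p.lat, "lon": p.lon, "mld_m": pp.mld, "zeu_m": pp.zeu,
            "int_chl_mg_m2": pp.integrated_chl,
            "integration_depth_m": pp.integration_depth,
            "flags": ";".join(pp.flags),
        })
    return pd.DataFrame(rows)
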