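"""Bloom phenology: annual cycles, 20-day binning, magnitude and typing.

Each float record is split into annual cycles starting 1 July (the austral
winter minimum).  A cycle qualifies when at least eight profiles fall inside
the bloom window (1 November - end of February).  Qualified cycles are
binned into 20-day periods anchored at the cycle start; the bloom magnitude
is the maximum over bins of the bin-mean depth-integrated chlorophyll, with
the bloom date at the centre of the winning bin and the bloom position the
mean float position inside it.

Blooms are classified by a precedence rule — island/plateau (downstream
shallow-source iron delivery) > seasonal sea ice > ocean ridge > HNLC — and
the magnitudes of the resulting groups are compared with a tie-corrected
Kruskal-Wallis H test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig, month_day
from .profiles import ProcessedProfile

log = logging.getLogger("ventbloom")

BLOOM_TYPES = ("island_plateau", "ice", "ridge", "HNLC")   # precedence order


@dataclass
class BloomCycle:
    float_id: str
    season_start: pd.Timestamp
    bins: pd.DataFrame           # bin_start, mean_int_chl, n_profiles
    qualified: bool
    magnitude: float = float("nan")       # mg m^-2
    magnitude_date: Optional[pd.Timestamp] = None
    magnitude_lat: float = float("nan")
    magnitude_lon: float = float("nan")


@dataclass
class BloomRecord:
    cycle: BloomCycle
    bloom_type: str


def _season_start_year(t: pd.Timestamp, start_month: int, start_day: int) -> int:
    if (t.month, t.day) >= (start_month, start_day):
        return t.year
    return t.year - 1


def split_annual_cycles(series: Sequence[ProcessedProfile],
                        cycle_start: str = "07-01") -> List[List[ProcessedProfile]]:
    """Group time-sorted profiles into annual cycles [1 Jul Y, 1 Jul Y+1)."""
    sm, sd = month_day(cycle_start)
    groups: Dict[int, List[ProcessedProfile]] = {}
    for pp in series:
        y = _season_start_year(pp.parent.time, sm, sd)
        groups.setdefault(y, []).append(pp)
    return [groups[y] for y in sorted(groups)]


def _window_bounds(season_year: int, window_start: str, window_end: str
                   ) -> Tuple[pd.Timestamp, pd.Timestamp]:
    ws_m, ws_d = month_day(window_start)
    we_m, we_d = month_day(window_end)
    start = pd.Timestamp(year=season_year, month=ws_m, day=ws_d)
    end_year = season_year if we_m >= ws_m else season_year + 1
    # late-February window end extends to 29 Feb in leap years
    if (we_m, we_d) == (2, 28) and pd.Timestamp(year=end_year, month=1, day=1).is_leap_year:
        we_d = 29
    end = pd.Timestamp(year=end_year, month=we_m, day=we_d) + pd.Timedelta(days=1)
    return start, end        # half-open [start, end)


def qualify_cycle(group: Sequence[ProcessedProfile], cfg: Optional[PipelineConfig] = None
                  ) -> bool:
    """True iff >= min_profiles profiles fall inside the bloom window."""
    cfg = cfg or PipelineConfig()
    if not group:
        return False
    sm, sd = month_day(cfg.cycle_start)
    year = _season_start_year(group[0].parent.time, sm, sd)
    start, end = _window_bounds(year, cfg.bloom_window_start, cfg.bloom_window_end)
    n = sum(1 for pp in group if start <= pp.parent.time < end)
    return n >= cfg.min_profiles


def bin_and_magnitude(group: Sequence[ProcessedProfile],
                      cfg: Optional[PipelineConfig] = None) -> BloomCycle:
    """20-day binning and bloom magnitude of one annual cycle.

    Bins are anchored at the season start so edges are reproducible across
    floats; the per-bin statistic is the mean of the profiles' integrated
    chlorophyll; the magnitude is the maximum bin mean.
    """
    cfg = cfg or PipelineConfig()
    sm, sd = month_day(cfg.cycle_start)
    year = _season_start_year(group[0].parent.time, sm, sd)
    season_start = pd.Timestamp(year=year, month=sm, day=sd)
    qualified = qualify_cycle(group, cfg)

    rows = []
    for pp in group:
        if np.isfinite(pp.integrated_chl):
            days = (pp.parent.time - season_start).total_seconds() / 86400.0
            rows.append({"bin": int(days // cfg.bin_days),
                         "int_chl": pp.integrated_chl,
                         "lat": pp.parent.lat, "lon": pp.parent.lon})
    if not rows:
        return BloomCycle(float_id=group[0].parent.float_id,
                          season_start=season_start,
                          bins=pd.DataFrame(columns=["bin_start", "mean_int_chl",
                                                     "n_profiles"]),
                          qualified=False)
    df = pd.DataFrame(rows)
    agg = df.groupby("bin").agg(mean_int_chl=("int_chl", "mean"),
                                n_profiles=("int_chl", "size"),
                                lat=("lat", "mean"), lon=("lon", "mean"))
    agg = agg.reset_index()
    agg["bin_start"] = [season_start + pd.Timedelta(days=cfg.bin_days * b)
                        for b in agg["bin"]]
    cyc = BloomCycle(float_id=group[0].parent.float_id, season_start=season_start,
                     bins=agg[["bin_start", "mean_int_chl", "n_profiles"]],
                     qualified=qualified)
    if qualified:
        k = int(agg["mean_int_chl"].idxmax())
        cyc.magnitude = float(agg.loc[k, "mean_int_chl"])
        cyc.magnitude_date = agg.loc[k, "bin_start"] + pd.Timedelta(
            days=cfg.bin_days / 2.0)
        cyc.magnitude_lat = float(agg.loc[k, "lat"])
        cyc.magnitude_lon = float(agg.loc[k, "lon"])
    return cyc


def classify_bloom(cycle: BloomCycle, masks: Dict[str, "object"]) -> str:
    """Bloom type by precedence island_plateau > ice > ridge > HNLC.

    ``masks`` maps type name -> boolean lookup; each lookup is either an
    xarray DataArray (lat/lon grid, nearest-node membership) or any object
    with a ``contains(lon, lat)`` method.  Positions outside a mask's domain
    count as not-member for that mask; a position outside every mask domain
    raises ValueError (unclassifiable).
    """
    lon, lat = cycle.magnitude_lon, cycle.magnitude_lat
    if not (np.isfinite(lon) and np.isfinite(lat)):
        raise ValueError("cycle has no magnitude position (unqualified?)")
    any_domain = False
    for btype in ("island_plateau", "ice", "ridge"):
        mask = masks.get(btype)
        if mask is None:
            continue
        inside, in_domain = _mask_member(mask, lon, lat)
        any_domain = any_domain or in_domain
        if inside:
            return btype
    if not any_domain and masks:
        raise ValueError(f"position ({lon:.2f}, {lat:.2f}) outside all mask domains")
    return "HNLC"


def _mask_member(mask, lon: float, lat: float) -> Tuple[bool, bool]:
    if hasattr(mask, "contains"):
        return bool(mask.contains(lon, lat)), True
    lats = mask["lat"].values
    lons = mask["lon"].values
    if not (lats.min() - 1 <= lat <= lats.max() + 1
            and lons.min() - 1 <= lon <= lons.max() + 1):
        return False, False
    j = int(np.argmin(np.abs(lats - lat)))
    i = int(np.argmin(np.abs(lons - lon)))
    return bool(np.asarray(mask.values)[j, i]), True


def compare_types(records: Sequence[BloomRecord]):
    """Kruskal-Wallis H test across bloom types plus per-type summaries.

    Requires at least two types with two or more records each; returns
    (H, p, summary DataFrame with count/mean/quartiles per type).
    """
    by_type: Dict[str, List[float]] = {}
    for r in records:
        by_type.setdefault(r.bloom_type, []).append(r.cycle.magnitude)
    groups = {k: v for k, v in by_type.items() if len(v) >= 2}
    if len(groups) < 2:
        raise ValueError("need >= 2 bloom types with >= 2 records each")
    h, p = stats.kruskal(*groups.values())
    rows = []
    for k, v in groups.items():
        arr = np.asarray(v)
        rows.append({"bloom_type": k, "n": arr.size, "mean": arr.mean(),
                     "q25": np.percentile(arr, 25),
                     "median": np.percentile(arr, 50),
                     "q75": np.percentile(arr, 75)})
    return float(h), float(p), pd.DataFrame(rows).set_index("bloom_type")


def blooms_to_frame(records: Sequence[BloomRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        c = r.cycle
        rows.append({"float_id": c.float_id,
                     "season_start": c.season_start.date().isoformat(),
                     "bloom_type": r.bloom_type,
                     "magnitude_mg_m2": c.magnitude,
                     "magnitude_date": (c.magnitude_date.date().isoformat()
                                        if c.magnitude_date is not None else ""),
                     "lat": c.magnitude_lat, "lon": c.magnitude_lon})
    return pd.DataFrame(rows)
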