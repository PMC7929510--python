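"""Standardisation of raw tracks to analysis-ready daily positions.

Steps, in pipeline order: subsample each track to one fix per local (solar)
day, nearest local noon; truncate each track to the 365 days following
device attachment; apply optional device-specific filters to GLS tracks;
and flag population-months with too little data to be representative.
"""

from __future__ import annotations

import datetime as dt
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .data_model import Device, Fix, Track
from .geo import haversine_km

log = logging.getLogger(__name__)

#: Approximate day-of-year of the March and September equinoxes.
EQUINOX_DOY = (79, 265)


def solar_offset_hours(lon: float) -> float:
    """Longitude-proportional offset of local solar time from UTC (h)."""
    return lon / 15.0


def local_day(fix: Fix, use_solar: bool = True) -> dt.date:
    """Local calendar date of a fix under the solar-offset rule."""
    offset = solar_offset_hours(fix.lon) if use_solar else 0.0
    return (fix.timestamp + dt.timedelta(hours=offset)).date()


def _noon_distance_s(fix: Fix, day: dt.date, use_solar: bool) -> float:
    offset = solar_offset_hours(fix.lon) if use_solar else 0.0
    local = fix.timestamp + dt.timedelta(hours=offset)
    noon = dt.datetime.combine(day, dt.time(12), tzinfo=local.tzinfo)
    return abs((local - noon).total_seconds())


@dataclass
class DailyTrack:
    """A track reduced to at most one representative fix per local day."""

    bird_id: str
    species_id: str
    population_id: str
    device: Device
    local_days: list[dt.date]
    fixes: list[Fix]

    def __post_init__(self) -> None:
        if len(self.local_days) != len(self.fixes):
            raise ValueError("local_days and fixes length mismatch")
        if any(b <= a for a, b in zip(self.local_days, self.local_days[1:])):
            raise ValueError("local_days not strictly increasing")

    def __len__(self) -> int:
        return len(self.fixes)


def subsample_daily(track: Track, use_solar: bool = True) -> DailyTrack:
    """Keep, for each local day, the fix nearest local noon.

    Local time is UTC + lon/15 hours (solar convention; set
    ``use_solar=False`` for plain UTC days). Ties are broken by the earliest
    timestamp, making the operation deterministic and idempotent.
    """
    best: dict[dt.date, tuple[float, dt.datetime, Fix]] = {}
    for fix in track.fixes:
        day = local_day(fix, use_solar)
        key = (_noon_distance_s(fix, day, use_solar), fix.timestamp)
        if day not in best or key < best[day][:2]:
            best[day] = (key[0], key[1], fix)
    days = sorted(best)
    return DailyTrack(
        bird_id=track.bird_id, species_id=track.species_id,
        population_id=track.population_id, device=track.device,
        local_days=days, fixes=[best[d][2] for d in days],
    )


def truncate_breeding_year(track: Track, n_days: int = 365) -> Track:
    """Drop fixes dated after attachment_date + (n_days - 1) calendar days."""
    cutoff = track.attachment_date + dt.timedelta(days=n_days - 1)
    kept = [f for f in track.fixes if f.timestamp.date() <= cutoff]
    return Track(bird_id=track.bird_id, species_id=track.species_id,
                 population_id=track.population_id, device=track.device,
                 fixes=kept, attachment_date=track.attachment_date)


@dataclass
class GlsFilterParams:
    """Configurable GLS filter chain; defaults are artifact stand-ins.

    ``filter_order`` is recorded in the report because the chain is not
    order-independent.
    """

    equinox_enabled: bool = True
    equinox_window_days: int = 15
    equinox_keep_lon: bool = False
    speed_enabled: bool = True
    max_km_per_day: float = 1000.0
    filter_order: tuple[str, ...] = ("equinox", "speed")


@dataclass
class GlsFilterReport:
    filter_order: tuple[str, ...]
    n_in: int = 0
    n_out: int = 0
    dropped: dict = field(default_factory=dict)


def _doy_distance(day: dt.date, doy: int) -> int:
    year_len = 366 if day.year % 4 == 0 and (day.year % 100 != 0 or day.year % 400 == 0) else 365
    d = abs(day.timetuple().tm_yday - doy)
    return min(d, year_len - d)


def near_equinox(day: dt.date, window_days: int) -> bool:
    return any(_doy_distance(day, doy) <= window_days for doy in EQUINOX_DOY)


def _equinox_filter(fixes: list[Fix], params: GlsFilterParams) -> list[Fix]:
    if params.equinox_keep_lon:
        # Latitude is unreliable near the equinoxes; substitute the latitude
        # of the nearest out-of-window fix and keep the longitude as observed.
        ok_lats = [(f.timestamp, f.lat) for f in fixes
                   if not near_equinox(f.timestamp.date(), params.equinox_window_days)]
        if not ok_lats:
            return []
        out = []
        for f in fixes:
            if near_equinox(f.timestamp.date(), params.equinox_window_days):
                lat = min(ok_lats, key=lambda tl: abs((tl[0] - f.timestamp).total_seconds()))[1]
                f = Fix(f.bird_id, f.timestamp, f.lon, lat, f.device)
            out.append(f)
        return out
    return [f for f in fixes
            if not near_equinox(f.timestamp.date(), params.equinox_window_days)]


def _speed_filter(fixes: list[Fix], params: GlsFilterParams) -> list[Fix]:
    kept: list[Fix] = []
    for f in fixes:
        if not kept:
            kept.append(f)
            continue
        prev = kept[-1]
        days = (f.timestamp - prev.timestamp).total_seconds() / 86400.0
        dist = float(haversine_km(prev.lon, prev.lat, f.lon, f.lat))
        if days <= 0 or dist / max(days, 1e-9) <= params.max_km_per_day:
            kept.append(f)
    return kept


def filter_gls(track: Track, params: Optional[GlsFilterParams] = None,
               ) -> tuple[Track, GlsFilterReport]:
    """Apply the configured GLS filter chain to one track.

    Non-GLS tracks are returned unchanged with a warning: their positional
    error does not warrant these filters.
    """
    params = params or GlsFilterParams()
    report = GlsFilterReport(filter_order=params.filter_order, n_in=len(track))
    if track.device is not Device.GLS:
        warnings.warn(f"filter_gls called on {track.device.value} track "
                      f"{track.bird_id!r}; returned unchanged")
        report.n_out = len(track)
        return track, report

    fixes = list(track.fixes)
    steps = {"equinox": (_equinox_filter, params.equinox_enabled),
             "speed": (_speed_filter, params.speed_enabled)}
    for name in params.filter_order:
        fn, enabled = steps[name]
        if not enabled:
            continue
        before = len(fixes)
        fixes = fn(fixes, params)
        report.dropped[name] = before - len(fixes)
    report.n_out = len(fixes)
    if not fixes:
        raise ValueError(f"track {track.bird_id!r}: all fixes removed by GLS filters")
    out = Track(bird_id=track.bird_id, species_id=track.species_id,
                population_id=track.population_id, device=track.device,
                fixes=fixes, attachment_date=track.attachment_date)
    return out, report


def daily_frame(daily_tracks: Iterable[DailyTrack]) -> pd.DataFrame:
    """Flatten daily tracks to one row per (bird, local day)."""
    rows = []
    for t in daily_tracks:
        for day, fix in zip(t.local_days, t.fixes):
            rows.append((t.bird_id, t.species_id, t.population_id,
                         t.device.value, day, day.month, fix.lon, fix.lat))
    return pd.DataFrame(rows, columns=["bird_id", "species_id", "population_id",
                                       "device", "local_day", "month", "lon", "lat"])


def representativeness_mask(daily: pd.DataFrame, min_days: int = 10,
                            min_individuals: int = 0) -> pd.DataFrame:
    """Flag which (population, calendar month) cells carry enough data.

    Months are pooled across years. A cell is retained iff it has at least
    ``min_days`` unique tracking days and at least ``min_individuals``
    distinct birds (the conservative variant uses 10 and 5).
    """
    g = daily.groupby(["population_id", "month"]).agg(
        n_tracking_days=("local_day", "nunique"),
        n_individuals=("bird_id", "nunique"),
    ).reset_index()
    g["retained"] = ((g["n_tracking_days"] >= min_days)
                     & (g["n_individuals"] >= min_individuals))
    return g


def apply_mask(daily: pd.DataFrame, mask: pd.DataFrame) -> pd.DataFrame:
    """Drop rows of masked-out population-months."""
    keep = mask.loc[mask["retained"], ["population_id", "month"]]
    return daily.merge(keep, on=["population_id", "month"], how="inner")


def months_covered(mask: pd.DataFrame) -> pd.Series:
    """Number of retained calendar months per population (m_max bookkeeping)."""
    return (mask[mask["retained"]].groupby("population_id")["month"]
            .nunique().rename("months_covered"))
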