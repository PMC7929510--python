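"""Population-weighted occupancy estimation.

The estimator works month by month: for each tracked individual the
proportion of its tracked days spent in each zone, averaged over the
individuals of a breeding population and scaled by the population size N_p
to give bird-months (T_spme). Monthly totals are summed over the retained
months and divided by 12 — untracked months deliberately contribute zero —
to give annual time spent per zone in bird-years (T_e).

Also here: zone species richness split into breeding / visiting / both,
the richness-underestimation audit, gridded surfaces, and per-species
tracking-coverage statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .data_model import (
    HIGH_SEAS_ID,
    BreedingPopulation,
    Layer,
    SpeciesInfo,
    ZoneLayer,
)
from .grid import HexGrid

__all__ = [
    "monthly_proportions",
    "rfmo_monthly_proportions",
    "add_population_time",
    "annual_time",
    "RichnessRecord",
    "richness_by_zone",
    "richness_underestimation",
    "GridSurface",
    "grid_aggregate",
    "coverage_table",
]

_KEYS = ["population_id", "month"]


def _proportion_table(num: pd.DataFrame, den: pd.DataFrame,
                      zone_col: str) -> pd.DataFrame:
    """Mean over individuals of per-zone day proportions, per population-month.

    ``den`` supplies each individual's total tracked days in the month
    (D_im); ``num`` supplies the per-zone day counts (D_ime). The mean
    divides by the number of individuals tracked that month (n_m), so zones
    an individual never visited count as zero for that individual.
    """
    d_im = den.groupby(_KEYS + ["bird_id"])["local_day"].nunique().rename("d_im")
    d_ime = (num.groupby(_KEYS + ["bird_id", zone_col])["local_day"]
             .nunique().rename("d_ime").reset_index())
    d_ime = d_ime.merge(d_im.reset_index(), on=_KEYS + ["bird_id"])
    d_ime["prop"] = d_ime["d_ime"] / d_ime["d_im"]

    n_m = den.groupby(_KEYS)["bird_id"].nunique().rename("n_individuals")
    out = (d_ime.groupby(_KEYS + [zone_col])["prop"].sum().rename("sum_prop")
           .reset_index().merge(n_m.reset_index(), on=_KEYS))
    out["mean_prop"] = out["sum_prop"] / out["n_individuals"]
    out = out.rename(columns={zone_col: "zone_id"})
    return out[["population_id", "month", "zone_id", "mean_prop", "n_individuals"]]


def monthly_proportions(assignments: pd.DataFrame,
                        mask: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Country-layer mean occupancy proportions per (population, month, zone).

    ``assignments`` is a daily frame with a ``country_zone`` column (one row
    per bird-day). If a representativeness mask is given, masked-out
    population-months are dropped first. Per population-month the returned
    ``mean_prop`` sums to 1 across zones.
    """
    df = assignments
    if mask is not None:
        keep = mask.loc[mask["retained"], ["population_id", "month"]]
        df = df.merge(keep, on=["population_id", "month"], how="inner")
    return _proportion_table(df, df, "country_zone")


def rfmo_monthly_proportions(assignments: pd.DataFrame,
                             mask: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """RFMO-layer proportions computed over high-seas days only.

    Denominators stay the individual's total tracked days in the month, so
    proportions remain fractions of the whole month. Because competence
    areas overlap, a day may count toward several RFMOs and per-RFMO totals
    are not additive.
    """
    df = assignments
    if mask is not None:
        keep = mask.loc[mask["retained"], ["population_id", "month"]]
        df = df.merge(keep, on=["population_id", "month"], how="inner")
    hs = df[df["country_zone"] == HIGH_SEAS_ID].copy()
    hs = hs[hs["rfmo_zones"].map(len) > 0]
    if hs.empty:
        return pd.DataFrame(columns=["population_id", "month", "zone_id",
                                     "mean_prop", "n_individuals"])
    hs = hs.explode("rfmo_zones").rename(columns={"rfmo_zones": "rfmo_zone"})
    return _proportion_table(hs, df, "rfmo_zone")


def add_population_time(monthly: pd.DataFrame,
                        populations: Iterable[BreedingPopulation]) -> pd.DataFrame:
    """Attach T_spme = mean_prop × N_p (bird-months, unrounded)."""
    np_by_pop = {p.population_id: p.n_adults for p in populations}
    out = monthly.copy()
    missing = set(out["population_id"]) - set(np_by_pop)
    if missing:
        raise KeyError(f"populations without size data: {sorted(missing)}")
    out["t_spme"] = out["mean_prop"] * out["population_id"].map(np_by_pop)
    return out


def annual_time(monthly: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annualise monthly bird-months to bird-years per zone.

    Returns ``(per_zone, per_zone_population)`` frames; ``t_e`` is the sum
    of T_spme over retained months and populations divided by 12 (months
    without tracking contribute zero — a conservative underestimate).
    """
    per_pop = (monthly.groupby(["zone_id", "population_id"])["t_spme"].sum()
               .rename("bird_months").reset_index())
    per_pop["bird_years"] = per_pop["bird_months"] / 12.0
    per_zone = (per_pop.groupby("zone_id")["bird_years"].sum()
                .rename("t_e").reset_index())
    return per_zone, per_pop


@dataclass(frozen=True)
class RichnessRecord:
    zone_id: str
    breeding_only: frozenset[str]
    visiting_only: frozenset[str]
    both: frozenset[str]

    @property
    def total(self) -> int:
        return len(self.breeding_only | self.visiting_only | self.both)


def richness_by_zone(assignments: pd.DataFrame,
                     populations: Iterable[BreedingPopulation],
                     country_layer: ZoneLayer) -> list[RichnessRecord]:
    """Species richness per country-layer zone in three disjoint categories.

    Breeding species of a zone are those with a tracked colony whose origin
    country owns the zone; a breeding species also visited by conspecifics
    of other breeding origins counts in ``both``; species occurring with no
    local breeding count as visiting. Zones without a sovereign (high seas,
    Antarctic, disputed) can only have visiting species.
    """
    pops = list(populations)
    origin_of = {p.population_id: p.origin_country for p in pops}
    breeding_by_country: dict[str, set[str]] = {}
    for p in pops:
        breeding_by_country.setdefault(p.origin_country, set()).add(p.species_id)

    df = assignments[["country_zone", "species_id", "population_id"]].drop_duplicates()
    df = df.assign(origin=df["population_id"].map(origin_of))

    records = []
    for zone in country_layer:
        sub = df[df["country_zone"] == zone.zone_id]
        present = set(sub["species_id"])
        breeding = breeding_by_country.get(zone.sovereign, set()) if zone.sovereign else set()
        visited_from_elsewhere = set(
            sub.loc[sub["origin"] != (zone.sovereign or ""), "species_id"])
        both = breeding & visited_from_elsewhere
        records.append(RichnessRecord(
            zone_id=zone.zone_id,
            breeding_only=frozenset(breeding - both),
            visiting_only=frozenset(present - breeding),
            both=frozenset(both)))
    return records


def richness_underestimation(records: Iterable[RichnessRecord],
                             species_info: Iterable[SpeciesInfo],
                             ) -> tuple[pd.DataFrame, float, float]:
    """Audit tracked breeding richness against known breeding-country lists.

    Returns the per-country table plus the mean and SD of the shortfall.
    Tracked breeding richness exceeding the known list is a data
    inconsistency and raises.
    """
    known: dict[str, set[str]] = {}
    for s in species_info:
        for c in s.known_breeding_countries:
            known.setdefault(c, set()).add(s.species_id)
    tracked = {r.zone_id: set(r.breeding_only | r.both) for r in records}

    rows = []
    for country in sorted(known):
        kn, tr = known[country], tracked.get(country, set())
        extra = tr - kn
        if extra:
            raise ValueError(f"country {country!r}: tracked breeding species "
                             f"{sorted(extra)} not in known breeding list")
        rows.append((country, len(kn), len(tr), len(kn) - len(tr)))
    df = pd.DataFrame(rows, columns=["country", "n_known", "n_tracked", "delta"])
    if df.empty:
        return df, 0.0, 0.0
    return df, float(df["delta"].mean()), float(df["delta"].std(ddof=1)) if len(df) > 1 else 0.0


@dataclass
class GridSurface:
    grid: HexGrid
    values: dict[str, np.ndarray]

    def to_geojson(self) -> dict:
        return self.grid.to_geojson(self.values)


def grid_aggregate(daily: pd.DataFrame, grid: HexGrid,
                   populations: Optional[Iterable[BreedingPopulation]] = None,
                   statistic: str = "richness",
                   monthly: bool = False) -> GridSurface:
    """Bin daily positions onto the hexagonal grid.

    ``statistic='richness'`` counts distinct species with at least one daily
    fix per cell; ``statistic='time'`` reruns the occupancy estimator with
    the grid cell playing the role of the maritime zone, yielding bird-years
    per cell that sum (by construction) to the country-layer total. With
    ``monthly=True`` one surface per calendar month is produced.
    """
    df = daily.copy()
    df["cell"] = grid.cell_of(df["lon"].to_numpy(), df["lat"].to_numpy())
    values: dict[str, np.ndarray] = {}

    def one(sub: pd.DataFrame, suffix: str = "") -> None:
        if statistic == "richness":
            counts = sub.groupby("cell")["species_id"].nunique()
            arr = np.zeros(grid.n_cells)
            arr[counts.index.to_numpy()] = counts.to_numpy()
            values["richness" + suffix] = arr
        elif statistic == "time":
            if populations is None:
                raise ValueError("statistic='time' needs population sizes")
            m = _proportion_table(sub, sub, "cell")
            m = add_population_time(m, populations)
            per_zone, _ = annual_time(m)
            arr = np.zeros(grid.n_cells)
            arr[per_zone["zone_id"].to_numpy(int)] = per_zone["t_e"].to_numpy()
            values["bird_years" + suffix] = arr
        else:
            raise ValueError(f"unknown statistic {statistic!r}")

    if monthly:
        for month, sub in df.groupby("month"):
            one(sub, f"_m{int(month):02d}")
    else:
        one(df)
    return GridSurface(grid=grid, values=values)


def coverage_table(populations: Iterable[BreedingPopulation],
                   species_info: Iterable[SpeciesInfo],
                   months_covered: pd.Series,
                   n_birds: Optional[pd.Series] = None) -> pd.DataFrame:
    """Per-species tracking coverage of population and annual cycle.

    ``pct_pop`` is the tracked share of the global breeding population;
    ``pct_year_known`` additionally down-weights each population by its
    covered fraction of the year (months_covered / 12).
    """
    pops = list(populations)
    rows = []
    for s in species_info:
        mine = [p for p in pops if p.species_id == s.species_id]
        tracked_np = sum(p.n_adults for p in mine)
        known_time = sum(
            p.n_adults * float(months_covered.get(p.population_id, 0)) / 12.0
            for p in mine)
        pct_pop = 100.0 * tracked_np / s.n_global
        pct_known = 100.0 * known_time / s.n_global
        rows.append({
            "species_id": s.species_id,
            "n_sites": len(mine),
            "n_birds": int(n_birds.get(s.species_id, 0)) if n_birds is not None else pd.NA,
            "n_global": s.n_global,
            "pct_pop": pct_pop,
            "pct_year_known": pct_known,
            "pct_year_unknown": 100.0 - pct_known,
        })
    return pd.DataFrame(rows)
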