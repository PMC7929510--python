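"""Readers and writers for the tabular and geospatial formats the pipeline touches.

Tracking tables are CSV with a configurable column mapping (archive exports
differ in header names); zones are GeoJSON feature collections carrying
``zone_id``/``layer``/``sovereign``/``claimants``/``disputed`` properties.
Readers validate aggressively: structural problems are hard errors, while
individually bad rows are dropped and counted in an :class:`IngestReport`.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd
from shapely.geometry import mapping, shape

from .data_model import (
    HIGH_SEAS_ID,
    BreedingPopulation,
    Device,
    Fix,
    Layer,
    LayerKind,
    MaritimeZone,
    SpeciesInfo,
    Track,
    ZoneLayer,
)
from .geo import WORLD, ensure_valid, normalize_lon, split_antimeridian, union_all

log = logging.getLogger(__name__)

#: Maximum pairwise overlap area (deg^2) tolerated between country-partition
#: zones before the layer is rejected as malformed.
PARTITION_OVERLAP_TOL = 1e-9


@dataclass
class TrackSchema:
    """Column mapping from an arbitrary tracking-table export to our fields."""

    bird_id: str = "bird_id"
    species_id: str = "species_id"
    population_id: str = "population_id"
    device: str = "device"
    timestamp: str = "timestamp"
    lon: str = "lon"
    lat: str = "lat"

    def required(self) -> list[str]:
        return [self.bird_id, self.species_id, self.population_id,
                self.device, self.timestamp, self.lon, self.lat]


@dataclass
class IngestReport:
    n_rows: int = 0
    n_accepted: int = 0
    n_rejected: int = 0
    reasons: Counter = field(default_factory=Counter)

    def reject(self, reason: str, n: int = 1) -> None:
        self.n_rejected += n
        self.reasons[reason] += n


def read_tracks(path, schema: Optional[TrackSchema] = None) -> tuple[list[Track], IngestReport]:
    """Read a tracking CSV into validated, time-sorted per-bird tracks.

    Rows with unparseable timestamps or out-of-range coordinates are dropped
    and tallied; a missing required column is a hard error.
    """
    schema = schema or TrackSchema()
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in schema.required() if c not in df.columns]
    if missing:
        raise ValueError(f"tracking table {path}: missing required column(s) {missing}")

    report = IngestReport(n_rows=len(df))
    ts = pd.to_datetime(df[schema.timestamp], errors="coerce", utc=True,
                        format="mixed")
    lon = pd.to_numeric(df[schema.lon], errors="coerce").map(
        lambda x: normalize_lon(x) if pd.notna(x) else x)
    lat = pd.to_numeric(df[schema.lat], errors="coerce")

    bad_ts = ts.isna()
    bad_coord = lon.isna() | lat.isna() | (lat < -90) | (lat > 90)
    bad_dev = ~df[schema.device].isin([d.value for d in Device])
    report.reject("unparseable timestamp", int(bad_ts.sum()))
    report.reject("invalid coordinate", int((bad_coord & ~bad_ts).sum()))
    report.reject("unknown device", int((bad_dev & ~bad_ts & ~bad_coord).sum()))
    keep = ~(bad_ts | bad_coord | bad_dev)
    if report.n_rejected:
        log.warning("read_tracks: dropped %d of %d rows (%s)",
                    report.n_rejected, report.n_rows, dict(report.reasons))

    clean = pd.DataFrame({
        "bird_id": df[schema.bird_id], "species_id": df[schema.species_id],
        "population_id": df[schema.population_id], "device": df[schema.device],
        "timestamp": ts, "lon": lon, "lat": lat,
    })[keep].sort_values(["bird_id", "timestamp"], kind="mergesort")

    tracks: list[Track] = []
    for bird_id, grp in clean.groupby("bird_id", sort=True):
        grp = grp.drop_duplicates(subset="timestamp")
        dev = Device(grp["device"].iloc[0])
        fixes = [Fix(bird_id=str(bird_id), timestamp=t.to_pydatetime(),
                     lon=float(x), lat=float(y), device=dev)
                 for t, x, y in zip(grp["timestamp"], grp["lon"], grp["lat"])]
        tracks.append(Track(bird_id=str(bird_id),
                            species_id=str(grp["species_id"].iloc[0]),
                            population_id=str(grp["population_id"].iloc[0]),
                            device=dev, fixes=fixes))
    report.n_accepted = sum(len(t) for t in tracks)
    return tracks, report


def read_populations(pop_path, species_path,
                     pairs_to_individuals: bool = False,
                     ) -> tuple[list[BreedingPopulation], list[SpeciesInfo]]:
    """Read and cross-validate the breeding-population and species tables.

    Hard errors: a population referencing an unknown species, non-positive
    population size, or per-species sums of N_p exceeding the global N_s.
    Set ``pairs_to_individuals`` when the source reports breeding pairs.
    """
    pops_df = pd.read_csv(pop_path)
    spp_df = pd.read_csv(species_path)

    species: dict[str, SpeciesInfo] = {}
    for _, r in spp_df.iterrows():
        kbc = r.get("known_breeding_countries", "")
        kbc = frozenset(str(kbc).split(";")) if pd.notna(kbc) and str(kbc) else frozenset()
        species[str(r["species_id"])] = SpeciesInfo(
            species_id=str(r["species_id"]),
            common_name=str(r.get("common_name", "")),
            scientific_name=str(r.get("scientific_name", "")),
            n_global=float(r["n_global"]),
            biennial=bool(r.get("biennial", False)),
            known_breeding_countries=kbc,
        )

    scale = 2.0 if pairs_to_individuals else 1.0
    populations: list[BreedingPopulation] = []
    for _, r in pops_df.iterrows():
        sid = str(r["species_id"])
        if sid not in species:
            raise ValueError(
                f"population {r['population_id']!r} references unknown species {sid!r}")
        populations.append(BreedingPopulation(
            population_id=str(r["population_id"]), species_id=sid,
            island_group=str(r.get("island_group", "")),
            origin_country=str(r["origin_country"]),
            colony_lon=float(r["colony_lon"]), colony_lat=float(r["colony_lat"]),
            n_adults=float(r["n_adults"]) * scale,
        ))

    sums = Counter()
    for p in populations:
        sums[p.species_id] += p.n_adults
    for sid, total in sums.items():
        if total > species[sid].n_global * (1 + 1e-9):
            raise ValueError(
                f"species {sid!r}: sum of population sizes {total} exceeds "
                f"global population {species[sid].n_global}")
    return populations, list(species.values())


def _zone_from_feature(feat: dict) -> MaritimeZone:
    props = feat.get("properties") or {}
    if "zone_id" not in props or "layer" not in props:
        raise ValueError("zone feature missing 'zone_id' or 'layer' property")
    geom = shape(feat["geometry"])
    geom = split_antimeridian(ensure_valid(geom))
    claimants = props.get("claimants") or []
    if isinstance(claimants, str):
        claimants = [c for c in claimants.split(";") if c]
    return MaritimeZone(
        zone_id=str(props["zone_id"]), layer=Layer(props["layer"]), geometry=geom,
        sovereign=props.get("sovereign"), claimants=tuple(claimants),
        disputed=bool(props.get("disputed", False)),
    )


def read_zone_layer(path, layer_kind: LayerKind) -> ZoneLayer:
    """Read a GeoJSON feature collection into a validated :class:`ZoneLayer`.

    Geometry is repaired where possible and antimeridian-crossing polygons
    are split. For a country partition, pairwise overlaps between country
    zones beyond tolerance are a hard error, and a high-seas complement zone
    is synthesised if absent.
    """
    layer_kind = LayerKind(layer_kind)
    with open(path) as fh:
        fc = json.load(fh)
    if fc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    zones = [_zone_from_feature(f) for f in fc.get("features", [])]

    if layer_kind is LayerKind.COUNTRY_PARTITION:
        solid = [z for z in zones if z.layer is not Layer.HIGH_SEAS]
        for i, a in enumerate(solid):
            for b in solid[i + 1:]:
                inter = a.geometry.intersection(b.geometry)
                if inter.area > PARTITION_OVERLAP_TOL:
                    raise ValueError(
                        f"country partition {path}: zones {a.zone_id!r} and "
                        f"{b.zone_id!r} overlap (area {inter.area:.3g} deg^2)")
        if not any(z.layer is Layer.HIGH_SEAS for z in zones):
            hs_geom = WORLD.difference(union_all([z.geometry for z in solid]))
            zones.append(MaritimeZone(zone_id=HIGH_SEAS_ID, layer=Layer.HIGH_SEAS,
                                      geometry=hs_geom))
    return ZoneLayer(zones=zones, layer_kind=layer_kind)


def write_zone_layer(layer: ZoneLayer, path) -> None:
    feats = []
    for z in layer.zones:
        feats.append({
            "type": "Feature",
            "properties": {
                "zone_id": z.zone_id, "layer": z.layer.value,
                "sovereign": z.sovereign, "claimants": ";".join(z.claimants),
                "disputed": z.disputed,
            },
            "geometry": mapping(z.geometry) if z.geometry is not None else None,
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


# ---------------------------------------------------------------------------
# Tabular outputs. Column orders are fixed so reruns are byte-identical.

OCCUPANCY_COLUMNS = ["population_id", "month", "zone_id",
                     "mean_prop", "n_individuals", "t_spme"]
EDGE_COLUMNS = ["origin_country", "zone_id", "g_oe_percent", "n_species", "rank"]


def _check_outdir(path) -> None:
    d = os.path.dirname(os.fspath(path)) or "."
    if not os.path.isdir(d):
        raise FileNotFoundError(f"output directory does not exist: {d}")


def write_occupancy_csv(monthly: pd.DataFrame, path) -> None:
    _check_outdir(path)
    out = monthly[OCCUPANCY_COLUMNS].sort_values(
        ["population_id", "month", "zone_id"], kind="mergesort")
    out.to_csv(path, index=False)


def read_occupancy_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"population_id": str, "zone_id": str})


def write_edges_csv(edges: pd.DataFrame, path) -> None:
    _check_outdir(path)
    cols = [c for c in EDGE_COLUMNS if c in edges.columns]
    edges[cols].to_csv(path, index=False)


def write_assignments_csv(assignments: pd.DataFrame, path) -> None:
    _check_outdir(path)
    out = assignments.copy()
    out["rfmo_zones"] = out["rfmo_zones"].map(
        lambda s: ";".join(sorted(s)) if isinstance(s, (set, frozenset)) else (s or ""))
    out.to_csv(path, index=False)


def write_tracks_csv(tracks, path) -> None:
    _check_outdir(path)
    rows = []
    for t in tracks:
        for f in t.fixes:
            rows.append((t.bird_id, t.species_id, t.population_id,
                         t.device.value, f.timestamp.isoformat(), f.lon, f.lat))
    pd.DataFrame(rows, columns=["bird_id", "species_id", "population_id",
                                "device", "timestamp", "lon", "lat"]
                 ).to_csv(path, index=False)


def write_daily_csv(daily: pd.DataFrame, path) -> None:
    _check_outdir(path)
    daily.to_csv(path, index=False)


def read_daily_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"bird_id": str, "species_id": str,
                                  "population_id": str})
    df["local_day"] = pd.to_datetime(df["local_day"]).dt.date
    return df


def read_assignments_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"bird_id": str, "population_id": str,
                                  "species_id": str, "country_zone": str})
    df["local_day"] = pd.to_datetime(df["local_day"]).dt.date
    df["rfmo_zones"] = df["rfmo_zones"].map(
        lambda s: frozenset(str(s).split(";")) if pd.notna(s) and str(s) else frozenset())
    return df
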