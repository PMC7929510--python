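"""Construction of the two maritime-zone layers and daily zone assignment.

The country layer is an exhaustive partition of the globe: one zone per
sovereign country (land ∪ EEZ, dependencies aggregated under their
sovereign), standalone disputed-claim zones, a circum-Antarctic zone south
of the cutoff latitude, and a high-seas complement. The RFMO layer is an
overlay of competence areas clipped to the high seas; RFMO zones may
overlap each other, so a high-seas day can count toward several RFMOs at
once (per-RFMO totals are deliberately not additive).
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import box
from shapely.strtree import STRtree

from .data_model import (
    ANTARCTIC_ID,
    HIGH_SEAS_ID,
    BreedingPopulation,
    Fix,
    Layer,
    LayerKind,
    MaritimeZone,
    ZoneLayer,
    disputed_zone_id,
)
from .geo import WORLD, ensure_valid, split_antimeridian, union_all

log = logging.getLogger(__name__)

PARTITION_OVERLAP_TOL = 1e-9


@dataclass(frozen=True)
class AssignmentRecord:
    """Zone membership of one bird on one local day."""

    bird_id: str
    local_day: dt.date
    month: int
    country_zone: str
    rfmo_zones: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.rfmo_zones and self.country_zone != HIGH_SEAS_ID:
            raise ValueError("rfmo_zones must be empty unless in the high seas")


@dataclass(frozen=True)
class SovereigntyVariant:
    """One resolution of disputed-zone sovereignty for an analysis run."""

    variant_id: str
    mapping: tuple[tuple[str, str], ...] = ()  # (disputed zone_id -> sovereign)

    def as_dict(self) -> dict[str, str]:
        return dict(self.mapping)


def build_country_layer(eez_features: Sequence[dict],
                        land_features: Sequence[dict] = (),
                        territory_map: Optional[dict[str, str]] = None,
                        antarctic_lat: float = -60.0) -> ZoneLayer:
    """Build the exhaustive country/high-seas partition.

    Features are dicts with a shapely ``geometry`` plus either a
    ``territory`` name (resolved to its sovereign through ``territory_map``;
    identity for unmapped sovereign states is not assumed — a missing
    mapping is a hard error) or a ``claimants`` list marking a disputed
    area. Everything south of ``antarctic_lat`` is carved out of national
    zones into a single Antarctic zone; the high seas are the global
    complement.
    """
    territory_map = territory_map or {}
    by_sovereign: dict[str, list] = {}
    disputed: dict[tuple[str, ...], list] = {}
    for feat in list(eez_features) + list(land_features):
        geom = split_antimeridian(ensure_valid(feat["geometry"]))
        claimants = feat.get("claimants")
        if claimants:
            disputed.setdefault(tuple(sorted(claimants)), []).append(geom)
            continue
        terr = feat["territory"]
        if terr not in territory_map:
            raise ValueError(f"territory {terr!r} has no sovereign mapping")
        by_sovereign.setdefault(territory_map[terr], []).append(geom)

    antarctic = box(-180.0, -90.0, 180.0, antarctic_lat)
    disputed_union = union_all([g for gs in disputed.values() for g in gs])

    zones: list[MaritimeZone] = []
    for sovereign in sorted(by_sovereign):
        geom = union_all(by_sovereign[sovereign]).difference(antarctic)
        geom = geom.difference(disputed_union)
        zones.append(MaritimeZone(zone_id=sovereign, layer=Layer.COUNTRY,
                                  geometry=geom, sovereign=sovereign))
    for claimants in sorted(disputed):
        geom = union_all(disputed[claimants]).difference(antarctic)
        zones.append(MaritimeZone(zone_id=disputed_zone_id(claimants),
                                  layer=Layer.COUNTRY, geometry=geom,
                                  claimants=claimants, disputed=True))
    zones.append(MaritimeZone(zone_id=ANTARCTIC_ID, layer=Layer.ANTARCTIC,
                              geometry=antarctic))

    for i, a in enumerate(zones):
        for b in zones[i + 1:]:
            inter = a.geometry.intersection(b.geometry)
            if inter.area > PARTITION_OVERLAP_TOL:
                raise ValueError(f"country zones {a.zone_id!r} and {b.zone_id!r} "
                                 f"overlap (area {inter.area:.3g} deg^2)")

    hs_geom = WORLD.difference(union_all([z.geometry for z in zones]))
    zones.append(MaritimeZone(zone_id=HIGH_SEAS_ID, layer=Layer.HIGH_SEAS,
                              geometry=hs_geom))
    return ZoneLayer(zones=zones, layer_kind=LayerKind.COUNTRY_PARTITION)


def build_rfmo_layer(rfmo_features: Sequence[dict],
                     country_layer: ZoneLayer) -> ZoneLayer:
    """Clip RFMO competence areas to the high seas of the country layer.

    Overlaps between RFMO zones are preserved. An RFMO falling entirely
    inside national jurisdictions is retained with empty geometry and a
    warning so downstream joins stay total.
    """
    national = union_all([z.geometry for z in country_layer
                          if z.layer is not Layer.HIGH_SEAS])
    zones = []
    for feat in rfmo_features:
        geom = split_antimeridian(ensure_valid(feat["geometry"]))
        clipped = geom.difference(national)
        if clipped.is_empty or clipped.area == 0:
            log.warning("RFMO %r has no high-seas area after clipping",
                        feat["zone_id"])
        zones.append(MaritimeZone(zone_id=str(feat["zone_id"]), layer=Layer.RFMO,
                                  geometry=clipped))
    return ZoneLayer(zones=zones, layer_kind=LayerKind.RFMO_OVERLAY)


class ZoneIndex:
    """Spatial index over one zone layer for bulk point lookup."""

    def __init__(self, layer: ZoneLayer):
        self.layer = layer
        geoms, owners = [], []
        for z in layer:
            if z.layer is Layer.HIGH_SEAS or z.geometry is None or z.geometry.is_empty:
                continue
            parts = getattr(z.geometry, "geoms", [z.geometry])
            for part in parts:
                geoms.append(part)
                owners.append(z.zone_id)
        self._owners = np.array(owners, dtype=object)
        self._tree = STRtree(geoms) if geoms else None

    def query(self, lon: np.ndarray, lat: np.ndarray) -> list[set[str]]:
        """Set of covering zone_ids per point (boundary-inclusive)."""
        n = len(lon)
        hits: list[set[str]] = [set() for _ in range(n)]
        if self._tree is None:
            return hits
        pts = shapely.points(np.asarray(lon, float), np.asarray(lat, float))
        pi, ti = self._tree.query(pts, predicate="covered_by")
        for p, t in zip(pi, ti):
            hits[p].add(self._owners[t])
        return hits


def assign_day(fix: Fix, country_index: ZoneIndex,
               rfmo_index: Optional[ZoneIndex] = None,
               use_solar_day: bool = True) -> AssignmentRecord:
    """Assign a single daily fix to its country-layer zone and, if in the
    high seas, to every covering RFMO competence area.

    A point covered by several country-layer zones (possible only on shared
    boundaries) goes to the lexicographically smallest zone_id; a point
    covered by none is in the high seas.
    """
    from .preprocess import local_day

    day = local_day(fix, use_solar_day)
    czones = country_index.query(np.array([fix.lon]), np.array([fix.lat]))[0]
    country_zone = min(czones) if czones else HIGH_SEAS_ID
    rfmos: frozenset[str] = frozenset()
    if country_zone == HIGH_SEAS_ID and rfmo_index is not None:
        rfmos = frozenset(rfmo_index.query(np.array([fix.lon]),
                                           np.array([fix.lat]))[0])
    return AssignmentRecord(bird_id=fix.bird_id, local_day=day, month=day.month,
                            country_zone=country_zone, rfmo_zones=rfmos)


def assign_frame(daily: pd.DataFrame, country_layer: ZoneLayer,
                 rfmo_layer: Optional[ZoneLayer] = None) -> pd.DataFrame:
    """Vectorised zone assignment of a daily-position frame.

    Adds ``country_zone`` and ``rfmo_zones`` (frozenset, empty outside the
    high seas) columns to a copy of the input.
    """
    out = daily.copy()
    lon = out["lon"].to_numpy(float)
    lat = out["lat"].to_numpy(float)
    cidx = ZoneIndex(country_layer)
    chits = cidx.query(lon, lat)
    out["country_zone"] = [min(h) if h else HIGH_SEAS_ID for h in chits]

    rfmo_col: list[frozenset] = [frozenset()] * len(out)
    if rfmo_layer is not None:
        hs_mask = (out["country_zone"] == HIGH_SEAS_ID).to_numpy()
        if hs_mask.any():
            ridx = ZoneIndex(rfmo_layer)
            rhits = ridx.query(lon[hs_mask], lat[hs_mask])
            it = iter(rhits)
            rfmo_col = [frozenset(next(it)) if m else frozenset() for m in hs_mask]
    out["rfmo_zones"] = rfmo_col
    return out


def make_sovereignty_variants(country_layer: ZoneLayer,
                              populations: Iterable[BreedingPopulation],
                              ) -> list[SovereigntyVariant]:
    """Enumerate the paired analysis runs required by disputed colonies.

    Each disputed zone hosting a tracked colony must have exactly two
    claimants; the run is then duplicated with all such zones assigned to
    their first, respectively second, (alphabetical) claimant. Without
    disputed colonies a single identity variant is returned.
    """
    hosting: list[MaritimeZone] = []
    for z in country_layer:
        if not z.disputed or z.geometry is None:
            continue
        pts = [(p.colony_lon, p.colony_lat) for p in populations]
        if any(z.geometry.covers(shapely.points(x, y)) for x, y in pts):
            if len(z.claimants) != 2:
                raise ValueError(
                    f"disputed zone {z.zone_id!r} hosting a tracked colony has "
                    f"{len(z.claimants)} claimants; only bilateral disputes are supported")
            hosting.append(z)
    if not hosting:
        return [SovereigntyVariant(variant_id="baseline")]
    return [
        SovereigntyVariant(
            variant_id=f"claimant_{side + 1}",
            mapping=tuple((z.zone_id, sorted(z.claimants)[side]) for z in hosting),
        )
        for side in (0, 1)
    ]


def apply_variant(populations: Iterable[BreedingPopulation],
                  country_layer: ZoneLayer,
                  variant: SovereigntyVariant) -> list[BreedingPopulation]:
    """Reassign origin countries of colonies inside disputed zones."""
    mapping = variant.as_dict()
    if not mapping:
        return list(populations)
    out = []
    for p in populations:
        pt = shapely.points(p.colony_lon, p.colony_lat)
        new_origin = None
        for zid, sovereign in mapping.items():
            z = country_layer.get(zid)
            if z.geometry is not None and z.geometry.covers(pt):
                new_origin = sovereign
                break
        if new_origin is None:
            out.append(p)
        else:
            out.append(BreedingPopulation(
                population_id=p.population_id, species_id=p.species_id,
                island_group=p.island_group, origin_country=new_origin,
                colony_lon=p.colony_lon, colony_lat=p.colony_lat,
                n_adults=p.n_adults))
    return out
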