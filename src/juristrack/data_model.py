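"""Core domain types for the tracking → maritime-zone occupancy pipeline.

The pipeline moves through a small set of value objects: position fixes
grouped into per-bird :class:`Track` objects, breeding-population and
species metadata, and named maritime zones organised into two layers (an
exhaustive country/high-seas partition and an overlapping RFMO overlay).
Everything downstream (daily subsampling, zone assignment, occupancy and
connectivity estimation) consumes these types or flat pandas frames derived
from them.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Optional, Sequence

from shapely.geometry.base import BaseGeometry

__all__ = [
    "Device",
    "Layer",
    "LayerKind",
    "Fix",
    "Track",
    "BreedingPopulation",
    "SpeciesInfo",
    "MaritimeZone",
    "ZoneLayer",
    "HIGH_SEAS_ID",
    "ANTARCTIC_ID",
    "disputed_zone_id",
]

#: Reserved identifier of the implicit global-commons complement zone.
HIGH_SEAS_ID = "HIGH_SEAS"

#: Reserved identifier of the circum-polar zone south of the Antarctic cutoff.
ANTARCTIC_ID = "ANTARCTICA"


class Device(str, Enum):
    """Tracking device class; determines positional error handling."""

    GLS = "GLS"
    PTT = "PTT"
    GPS = "GPS"


class Layer(str, Enum):
    COUNTRY = "COUNTRY"
    HIGH_SEAS = "HIGH_SEAS"
    RFMO = "RFMO"
    ANTARCTIC = "ANTARCTIC"


class LayerKind(str, Enum):
    COUNTRY_PARTITION = "COUNTRY_PARTITION"
    RFMO_OVERLAY = "RFMO_OVERLAY"


def disputed_zone_id(claimants: Sequence[str]) -> str:
    """Canonical id for a zone with overlapping claims: ``disputed - A/B``."""
    return "disputed - " + "/".join(sorted(claimants))


@dataclass(frozen=True)
class Fix:
    """One timestamped position of one bird, WGS84 decimal degrees."""

    bird_id: str
    timestamp: dt.datetime
    lon: float
    lat: float
    device: Device

    def __post_init__(self) -> None:
        if not (-180.0 <= self.lon < 180.0):
            raise ValueError(f"lon {self.lon!r} outside [-180, 180)")
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"lat {self.lat!r} outside [-90, 90]")
        if not isinstance(self.timestamp, dt.datetime):
            raise TypeError("timestamp must be a datetime")
        object.__setattr__(self, "device", Device(self.device))


@dataclass
class Track:
    """Time-ordered sequence of fixes for one bird of one population."""

    bird_id: str
    species_id: str
    population_id: str
    device: Device
    fixes: list[Fix]
    attachment_date: Optional[dt.date] = None

    def __post_init__(self) -> None:
        if not self.fixes:
            raise ValueError(f"track {self.bird_id!r} has no fixes")
        self.device = Device(self.device)
        for f in self.fixes:
            if f.bird_id != self.bird_id:
                raise ValueError(
                    f"fix bird_id {f.bird_id!r} != track bird_id {self.bird_id!r}"
                )
        times = [f.timestamp for f in self.fixes]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"track {self.bird_id!r}: fixes not strictly increasing")
        if self.attachment_date is None:
            self.attachment_date = self.fixes[0].timestamp.date()

    def __len__(self) -> int:
        return len(self.fixes)

    def __iter__(self) -> Iterator[Fix]:
        return iter(self.fixes)


@dataclass(frozen=True)
class BreedingPopulation:
    """Individuals of one species breeding at one island group.

    ``n_adults`` is the breeding population size in individuals (the
    extrapolation weight N_p); sources reporting pairs must be doubled at
    ingest time.
    """

    population_id: str
    species_id: str
    island_group: str
    origin_country: str
    colony_lon: float
    colony_lat: float
    n_adults: float

    def __post_init__(self) -> None:
        if self.n_adults <= 0:
            raise ValueError(
                f"population {self.population_id!r}: n_adults must be > 0"
            )
        if not (-180.0 <= self.colony_lon < 180.0):
            raise ValueError(f"population {self.population_id!r}: bad colony_lon")
        if not (-90.0 <= self.colony_lat <= 90.0):
            raise ValueError(f"population {self.population_id!r}: bad colony_lat")


@dataclass(frozen=True)
class SpeciesInfo:
    """Species-level metadata: global size N_s and known breeding range."""

    species_id: str
    common_name: str = ""
    scientific_name: str = ""
    n_global: float = 0.0
    biennial: bool = False
    known_breeding_countries: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.n_global <= 0:
            raise ValueError(f"species {self.species_id!r}: n_global must be > 0")


@dataclass
class MaritimeZone:
    """A named multipolygon zone in one of the two analysis layers.

    ``geometry`` may be None for the implicit high-seas complement (it is
    the fallback of country-layer assignment and needs no polygon).
    """

    zone_id: str
    layer: Layer
    geometry: Optional[BaseGeometry] = None
    sovereign: Optional[str] = None
    claimants: tuple[str, ...] = ()
    disputed: bool = False

    def __post_init__(self) -> None:
        self.layer = Layer(self.layer)
        if self.disputed and not self.claimants:
            raise ValueError(f"zone {self.zone_id!r}: disputed but no claimants")
        if self.claimants and not self.disputed:
            raise ValueError(f"zone {self.zone_id!r}: claimants listed but not disputed")
        if self.layer is Layer.COUNTRY and not self.disputed and self.sovereign is None:
            raise ValueError(f"zone {self.zone_id!r}: COUNTRY zone needs a sovereign")


@dataclass
class ZoneLayer:
    """An ordered collection of zones forming one analysis layer."""

    zones: list[MaritimeZone]
    layer_kind: LayerKind

    def __post_init__(self) -> None:
        self.layer_kind = LayerKind(self.layer_kind)
        ids = [z.zone_id for z in self.zones]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate zone_id in layer")
        if self.layer_kind is LayerKind.RFMO_OVERLAY:
            bad = [z.zone_id for z in self.zones if z.layer is not Layer.RFMO]
            if bad:
                raise ValueError(f"non-RFMO zones in RFMO overlay: {bad}")

    def __iter__(self) -> Iterator[MaritimeZone]:
        return iter(self.zones)

    def __len__(self) -> int:
        return len(self.zones)

    @property
    def zone_ids(self) -> list[str]:
        return [z.zone_id for z in self.zones]

    def get(self, zone_id: str) -> MaritimeZone:
        for z in self.zones:
            if z.zone_id == zone_id:
                return z
        raise KeyError(zone_id)

    @property
    def high_seas(self) -> Optional[MaritimeZone]:
        for z in self.zones:
            if z.layer is Layer.HIGH_SEAS:
                return z
        return None
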