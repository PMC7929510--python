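"""Small geospatial helpers shared across modules.

All geometry is planar longitude/latitude (WGS84 degrees) with longitudes
normalised to [-180, 180); polygons that cross the antimeridian are split
into per-hemisphere parts at read time so every subsequent point-in-polygon
test is planar-safe.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
from shapely.geometry import GeometryCollection, MultiPolygon, Polygon, box
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union
from shapely.validation import make_valid

EARTH_RADIUS_KM = 6371.0088
KM_PER_DEG_LAT = math.pi * EARTH_RADIUS_KM / 180.0  # ~111.195

WORLD = box(-180.0, -90.0, 180.0, 90.0)


def normalize_lon(lon: float) -> float:
    """Wrap a longitude into [-180, 180)."""
    wrapped = (lon + 180.0) % 360.0 - 180.0
    # -180.0 and 180.0 are the same meridian; keep the canonical -180.0
    return -180.0 if wrapped == 180.0 else wrapped


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km; accepts scalars or numpy arrays."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def lonlat_to_xyz(lon, lat):
    """Unit-sphere Cartesian coordinates from degree lon/lat arrays."""
    lon = np.radians(np.asarray(lon, dtype=float))
    lat = np.radians(np.asarray(lat, dtype=float))
    return np.stack(
        [np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)], axis=-1
    )


def xyz_to_lonlat(xyz):
    xyz = np.asarray(xyz, dtype=float)
    lon = np.degrees(np.arctan2(xyz[..., 1], xyz[..., 0]))
    lat = np.degrees(np.arcsin(np.clip(xyz[..., 2], -1.0, 1.0)))
    return lon, lat


def _polygons(geom: BaseGeometry) -> list[Polygon]:
    if geom.is_empty:
        return []
    if isinstance(geom, Polygon):
        return [geom]
    if isinstance(geom, (MultiPolygon, GeometryCollection)):
        out: list[Polygon] = []
        for g in geom.geoms:
            out.extend(_polygons(g))
        return out
    return []


def ensure_valid(geom: BaseGeometry) -> BaseGeometry:
    """Repair an invalid geometry, keeping only the polygonal part."""
    if not geom.is_valid:
        geom = make_valid(geom)
    polys = _polygons(geom)
    if not polys:
        raise ValueError("geometry has no polygonal component after repair")
    return polys[0] if len(polys) == 1 else MultiPolygon(polys)


def _ring_crosses_antimeridian(coords: Iterable[tuple[float, float]]) -> bool:
    lons = [c[0] for c in coords]
    if any(x < -180.0 or x > 180.0 for x in lons):
        return True
    # a jump of exactly 360 links the identical -180/180 meridian (e.g. a
    # full-width ring touching both seam edges) and is not a crossing
    return any(180.0 < abs(b - a) < 360.0 for a, b in zip(lons, lons[1:]))


def split_antimeridian(geom: BaseGeometry) -> BaseGeometry:
    """Split polygons crossing the 180° meridian into per-hemisphere parts.

    Rings whose consecutive vertices jump by more than 180° of longitude are
    unwrapped onto a continuous [0, 360) frame, cut at lon 180, and the
    eastern part shifted back by 360. Geometries already inside
    [-180, 180) are returned unchanged.
    """
    polys = _polygons(geom)
    out: list[Polygon] = []
    for poly in polys:
        rings = [poly.exterior, *poly.interiors]
        if not any(_ring_crosses_antimeridian(r.coords) for r in rings):
            out.append(poly)
            continue

        def unwrap(coords):
            pts = [(normalize_lon(x), y) for x, y in coords]
            return [((x + 360.0) if x < 0.0 else x, y) for x, y in pts]

        shifted = Polygon(unwrap(poly.exterior.coords),
                          [unwrap(r.coords) for r in poly.interiors])
        shifted = ensure_valid(shifted)
        west = shifted.intersection(box(0.0, -90.0, 180.0, 90.0))
        east = shifted.intersection(box(180.0, -90.0, 360.0, 90.0))
        from shapely.affinity import translate

        east = translate(east, xoff=-360.0)
        out.extend(_polygons(west))
        out.extend(_polygons(east))
    if not out:
        raise ValueError("empty geometry after antimeridian split")
    return out[0] if len(out) == 1 else MultiPolygon(out)


def union_all(geoms: Iterable[BaseGeometry]) -> BaseGeometry:
    geoms = [g for g in geoms if g is not None and not g.is_empty]
    if not geoms:
        return Polygon()
    return unary_union(geoms)
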