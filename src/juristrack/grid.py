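"""Global quasi-hexagonal equal-area grid for mapping richness and time spent.

Cell centers are a spherical Fibonacci lattice sized so that the mean
great-circle spacing between Voronoi-neighbour centers hits a target
(default 495 km); cells are the spherical Voronoi regions of the centers.
The lattice gives near-identical cell areas (relative SD < 1%); a handful
of cells at the poles and the lattice's pentagon/heptagon cells are
unavoidable irregularities and are flagged via ``irregular``.
"""

from __future__ import annotations

import json
import math
from functools import cached_property

import numpy as np
from scipy.spatial import ConvexHull, SphericalVoronoi, cKDTree

from .geo import EARTH_RADIUS_KM, lonlat_to_xyz, xyz_to_lonlat

__all__ = ["HexGrid", "SPACING_TARGET_KM", "SPACING_TOL_KM"]

SPACING_TARGET_KM = 495.0
SPACING_TOL_KM = 30.0

#: Relative area deviation beyond which a cell is flagged irregular.
AREA_FLAG_TOL = 0.05


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Unit vectors of the n-point spherical Fibonacci lattice (midpoint rule)."""
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = np.arccos(np.clip(z, -1.0, 1.0))
    theta = 2.0 * np.pi * i / ((1.0 + math.sqrt(5.0)) / 2.0)
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta), z])


class HexGrid:
    """Voronoi grid over Fibonacci-lattice centers on the sphere."""

    def __init__(self, n_cells: int):
        if n_cells < 32:
            raise ValueError("grid needs at least 32 cells")
        self.n_cells = int(n_cells)
        self.centers_xyz = _fibonacci_sphere(self.n_cells)
        lon, lat = xyz_to_lonlat(self.centers_xyz)
        self.center_lon = lon
        self.center_lat = lat
        self._tree = cKDTree(self.centers_xyz)

    @classmethod
    def from_spacing(cls, target_km: float = SPACING_TARGET_KM,
                     tol_km: float = SPACING_TOL_KM) -> "HexGrid":
        """Build a grid whose realised mean neighbour spacing hits the target.

        The cell count follows from hexagonal packing (area per cell =
        sqrt(3)/2 * d^2); the realised mean is then verified against
        ``target_km`` ± ``tol_km`` and nearby cell counts are suggested if
        it falls outside.
        """
        area = math.sqrt(3.0) / 2.0 * target_km ** 2
        n = int(round(4.0 * math.pi * EARTH_RADIUS_KM ** 2 / area))
        grid = cls(n)
        realised = grid.mean_spacing_km
        if not (target_km - tol_km <= realised <= target_km + tol_km):
            options = {k: cls(k).mean_spacing_km
                       for k in (int(n * 0.9), n, int(n * 1.1))}
            raise ValueError(
                f"spacing target {target_km}±{tol_km} km unreachable: "
                f"n={n} realises {realised:.1f} km; nearby options {options}")
        return grid

    # -- neighbour structure -------------------------------------------------

    @cached_property
    def _edges(self) -> np.ndarray:
        """Unique Voronoi-neighbour pairs (Delaunay edges via the hull)."""
        hull = ConvexHull(self.centers_xyz)
        edges = set()
        for simplex in hull.simplices:
            for a, b in ((0, 1), (1, 2), (0, 2)):
                edges.add(tuple(sorted((int(simplex[a]), int(simplex[b])))))
        return np.array(sorted(edges), dtype=int)

    @cached_property
    def neighbor_counts(self) -> np.ndarray:
        return np.bincount(self._edges.ravel(), minlength=self.n_cells)

    @cached_property
    def spacing_km(self) -> np.ndarray:
        """Great-circle distances between all neighbouring cell centers."""
        a = self.centers_xyz[self._edges[:, 0]]
        b = self.centers_xyz[self._edges[:, 1]]
        dots = np.clip(np.sum(a * b, axis=1), -1.0, 1.0)
        return EARTH_RADIUS_KM * np.arccos(dots)

    @property
    def mean_spacing_km(self) -> float:
        return float(self.spacing_km.mean())

    @property
    def spacing_sd_km(self) -> float:
        return float(self.spacing_km.std())

    # -- cell geometry -------------------------------------------------------

    @cached_property
    def _voronoi(self) -> SphericalVoronoi:
        sv = SphericalVoronoi(self.centers_xyz, radius=1.0)
        sv.sort_vertices_of_regions()
        return sv

    @cached_property
    def areas_km2(self) -> np.ndarray:
        return self._voronoi.calculate_areas() * EARTH_RADIUS_KM ** 2

    @cached_property
    def irregular(self) -> np.ndarray:
        """Cells that are non-hexagonal or exceed the equal-area tolerance."""
        areas = self.areas_km2
        rel = np.abs(areas - areas.mean()) / areas.mean()
        return (self.neighbor_counts != 6) | (rel > AREA_FLAG_TOL)

    def cell_of(self, lon, lat) -> np.ndarray:
        """Index of the grid cell containing each point (nearest center)."""
        xyz = lonlat_to_xyz(np.asarray(lon, float), np.asarray(lat, float))
        _, idx = self._tree.query(np.atleast_2d(xyz))
        return idx

    def cell_id(self, index: int) -> str:
        return f"cell_{index:05d}"

    def to_geojson(self, values: dict[str, np.ndarray] | None = None) -> dict:
        """Cell polygons (antimeridian-split) with per-cell value properties."""
        from shapely.geometry import Polygon, mapping

        from .geo import split_antimeridian

        feats = []
        sv = self._voronoi
        for k, region in enumerate(sv.regions):
            verts = sv.vertices[region]
            lon, lat = xyz_to_lonlat(verts)
            # unwrap ring longitudes around the cell center to keep it contiguous
            lon = self.center_lon[k] + (lon - self.center_lon[k] + 180.0) % 360.0 - 180.0
            poly = Polygon(np.column_stack([lon, lat]))
            poly = split_antimeridian(poly)
            props = {"cell_id": self.cell_id(k),
                     "center_lon": float(self.center_lon[k]),
                     "center_lat": float(self.center_lat[k]),
                     "irregular": bool(self.irregular[k])}
            for name, arr in (values or {}).items():
                v = arr[k]
                props[name] = v.item() if hasattr(v, "item") else v
            feats.append({"type": "Feature", "properties": props,
                          "geometry": mapping(poly)})
        return {"type": "FeatureCollection", "features": feats}

    def write_geojson(self, path, values=None) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_geojson(values), fh)
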