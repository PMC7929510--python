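import datetime as dt

import numpy as np
import pytest

from juristrack.data_model import Device, Fix, Track
from juristrack.synthetic import (
    SimConfig,
    make_populations,
    make_world,
    simulate_tracks,
)

UTC = dt.timezone.utc


def make_fix(bird="b1", ts="2017-01-01T12:00:00", lon=0.0, lat=0.0, device="GPS"):
    return Fix(bird_id=bird, timestamp=dt.datetime.fromisoformat(ts).replace(tzinfo=UTC),
               lon=lon, lat=lat, device=Device(device))


def make_track(positions, bird="b1", species="sp_00", population="pop_000",
               device="GPS", attachment=None):
    """positions: iterable of (iso timestamp, lon, lat)."""
    fixes = [make_fix(bird, ts, lon, lat, device) for ts, lon, lat in positions]
    return Track(bird_id=bird, species_id=species, population_id=population,
                 device=Device(device), fixes=fixes, attachment_date=attachment)


@pytest.fixture(scope="session")
def toy_cfg():
    return SimConfig(seed=7, n_countries=2, n_rfmos=2, n_species=2,
                     populations_per_species=1, n_birds=6,
                     breeding_days=60, study_days=365)


@pytest.fixture(scope="session")
def toy_world(toy_cfg):
    return make_world(toy_cfg)


@pytest.fixture(scope="session")
def toy_pops(toy_cfg):
    return make_populations(toy_cfg)


@pytest.fixture(scope="session")
def toy_sim(toy_cfg, toy_world, toy_pops):
    populations, _ = toy_pops
    tracks, truth = simulate_tracks(toy_cfg, toy_world, populations)
    return tracks, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_sphere_lonlat(rng, n):
    """Uniform random points on the sphere, degree lon/lat."""
    lon = rng.uniform(-180.0, 180.0, n)
    lat = np.degrees(np.arcsin(rng.uniform(-1.0, 1.0, n)))
    return lon, lat


def spherical_polygon_area_km2(coords, radius_km=6371.0088, densify=200):
    """Independent spherical-area oracle.

    Treats edges as straight segments in lon/lat space, densifies them, and
    applies the shoelace formula in the cylindrical equal-area frame
    (x = lon_rad, y = sin(lat)), which preserves area exactly.
    """
    pts = []
    coords = list(coords)
    if coords[0] != coords[-1]:
        coords = coords + [coords[0]]
    for (x0, y0), (x1, y1) in zip(coords, coords[1:]):
        for t in np.linspace(0.0, 1.0, densify, endpoint=False):
            pts.append((x0 + t * (x1 - x0), y0 + t * (y1 - y0)))
    xs = np.radians([p[0] for p in pts])
    ys = np.sin(np.radians([p[1] for p in pts]))
    x2 = np.roll(xs, -1)
    y2 = np.roll(ys, -1)
    return abs(np.sum(xs * y2 - x2 * ys)) / 2.0 * radius_km ** 2


def ray_cast_contains(polygon_coords, holes, lon, lat):
    """Independent even-odd ray-casting point-in-polygon check (planar)."""

    def in_ring(ring, x, y):
        inside = False
        n = len(ring)
        for i in range(n):
            x0, y0 = ring[i]
            x1, y1 = ring[(i + 1) % n]
            if (y0 > y) != (y1 > y):
                xc = x0 + (y - y0) / (y1 - y0) * (x1 - x0)
                if x < xc:
                    inside = not inside
        return inside

    if not in_ring(polygon_coords, lon, lat):
        return False
    return not any(in_ring(h, lon, lat) for h in holes)
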