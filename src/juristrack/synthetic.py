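"""Synthetic worlds, populations, and tracks with known ground truth.

Everything here is a pure function of (config, seed): toy zone layers with
the structural properties the analysis assumes (an exhaustive country
partition plus an overlapping high-seas RFMO overlay), central-place +
migration movement simulation, device position error, estimator-recovery
reports, and the GLS-error sensitivity resampling.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import box

from .data_model import (
    BreedingPopulation,
    Device,
    Fix,
    SpeciesInfo,
    Track,
    ZoneLayer,
)
from .geo import KM_PER_DEG_LAT, normalize_lon
from .occupancy import (
    add_population_time,
    annual_time,
    monthly_proportions,
    richness_by_zone,
)
from .zones import assign_frame, build_country_layer, build_rfmo_layer

__all__ = [
    "SimConfig",
    "GroundTruth",
    "make_world",
    "make_populations",
    "simulate_tracks",
    "add_position_error",
    "recover_parameters",
    "gls_sensitivity",
]


@dataclass
class SimConfig:
    """Parameters of one synthetic experiment; seed fixes every RNG draw."""

    seed: int = 1
    n_countries: int = 2
    n_rfmos: int = 2
    n_species: int = 2
    populations_per_species: int = 1
    n_birds: int = 8                     # simulated individuals per population
    n_adults: float = 1000.0             # breeding population size N_p
    breeding_days: int = 120
    study_days: int = 365
    trip_radius_km: float = 250.0
    step_km: float = 200.0               # mean daily migration step
    n_waypoints: int = 2
    gls_fraction: float = 0.0            # fraction of birds carrying GLS tags
    gls_error_km: float = 186.0          # isotropic position error SD
    disputed: bool = False
    start_date: dt.date = dt.date(2015, 1, 1)
    country_lat: tuple[float, float] = (-30.0, 10.0)
    rfmo_lat: tuple[float, float] = (-55.0, -33.0)

    def __post_init__(self) -> None:
        if self.gls_error_km < 0:
            raise ValueError("gls_error_km must be >= 0")
        if self.n_countries < 1:
            raise ValueError("need at least one country")


def _country_name(i: int) -> str:
    return f"country_{chr(ord('A') + i)}" if i < 26 else f"country_{i}"


def make_world(config: SimConfig) -> tuple[ZoneLayer, ZoneLayer]:
    """Deterministic toy zone layers.

    Countries are longitude-banded boxes in a mid-latitude belt with a
    high-seas complement; RFMOs are boxes in a southern high-seas belt with
    consecutive overlap; optionally one disputed box (claimed by the first
    two countries) sits in the gap east of the first country.
    """
    n = config.n_countries
    slot = 360.0 / n
    width = slot * 0.5
    if width < 2.0:
        raise ValueError(f"{n} countries do not fit without overlap")
    lat0, lat1 = config.country_lat

    eez_features = []
    territory_map = {}
    for i in range(n):
        west = -180.0 + i * slot + slot * 0.1
        name = _country_name(i)
        territory_map[f"terr_{i}"] = name
        eez_features.append({"territory": f"terr_{i}",
                             "geometry": box(west, lat0, west + width, lat1)})
    if config.disputed:
        if n < 2:
            raise ValueError("a disputed zone needs two claimant countries")
        west = -180.0 + slot * 0.1 + width + slot * 0.1
        dwidth = min(slot * 0.15, 10.0)
        eez_features.append({
            "claimants": [_country_name(0), _country_name(1)],
            "geometry": box(west, lat0, west + dwidth, lat1)})

    country_layer = build_country_layer(eez_features, territory_map=territory_map)

    rlat0, rlat1 = config.rfmo_lat
    rfmo_features = []
    if config.n_rfmos:
        rslot = 360.0 / config.n_rfmos
        rwidth = rslot * 0.7  # > slot: consecutive RFMOs deliberately overlap
        for j in range(config.n_rfmos):
            west = -180.0 + j * rslot
            east = west + rwidth
            geom = box(west, rlat0, min(east, 180.0), rlat1)
            if east > 180.0:  # wrap the overhang across the antimeridian
                from shapely.ops import unary_union
                geom = unary_union([geom, box(-180.0, rlat0, east - 360.0, rlat1)])
            rfmo_features.append({"zone_id": f"rfmo_{j}", "geometry": geom})
    rfmo_layer = build_rfmo_layer(rfmo_features, country_layer)
    return country_layer, rfmo_layer


def make_populations(config: SimConfig,
                     ) -> tuple[list[BreedingPopulation], list[SpeciesInfo]]:
    """Colonies at country-box centers; species assigned round-robin.

    Global species sizes equal the sum of their synthetic populations, so
    share invariants (Σ_e G_soe = 1 under full coverage) hold exactly.
    """
    n = config.n_countries
    slot = 360.0 / n
    lat_c = sum(config.country_lat) / 2.0
    populations = []
    k = 0
    for s in range(config.n_species):
        for _ in range(config.populations_per_species):
            i = k % n
            lon_c = -180.0 + i * slot + slot * 0.1 + slot * 0.25
            populations.append(BreedingPopulation(
                population_id=f"pop_{k:03d}", species_id=f"sp_{s:02d}",
                island_group=f"isle_{k:03d}", origin_country=_country_name(i),
                colony_lon=lon_c, colony_lat=lat_c, n_adults=config.n_adults))
            k += 1
    species = []
    for s in range(config.n_species):
        mine = [p for p in populations if p.species_id == f"sp_{s:02d}"]
        species.append(SpeciesInfo(
            species_id=f"sp_{s:02d}", common_name=f"species {s}",
            scientific_name=f"Avis fictus {s}",
            n_global=sum(p.n_adults for p in mine),
            known_breeding_countries=frozenset(p.origin_country for p in mine)))
    return populations, species


def _km_offset(lon: float, lat: float, dx_km: float, dy_km: float,
               ) -> tuple[float, float]:
    """Apply a local-tangent-plane kilometre offset to a lon/lat point."""
    new_lat = float(np.clip(lat + dy_km / KM_PER_DEG_LAT, -89.5, 89.5))
    coslat = max(np.cos(np.radians(lat)), 1e-6)
    new_lon = normalize_lon(lon + dx_km / (KM_PER_DEG_LAT * coslat))
    return new_lon, new_lat


def add_position_error(lon: np.ndarray, lat: np.ndarray, error_km: float,
                       rng: np.random.Generator,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Isotropic Gaussian error (SD in km) in the local tangent plane."""
    lon = np.asarray(lon, float)
    lat = np.asarray(lat, float)
    if error_km == 0:
        return lon.copy(), lat.copy()
    dx = rng.normal(0.0, error_km, size=lon.shape)
    dy = rng.normal(0.0, error_km, size=lat.shape)
    new_lat = np.clip(lat + dy / KM_PER_DEG_LAT, -89.5, 89.5)
    coslat = np.maximum(np.cos(np.radians(lat)), 1e-6)
    new_lon = np.array([normalize_lon(v) for v in lon + dx / (KM_PER_DEG_LAT * coslat)])
    return new_lon, new_lat


@dataclass
class GroundTruth:
    """True per-zone occupancy computed from all simulated individuals."""

    proportions: pd.DataFrame      # population_id, month, zone_id, mean_prop
    true_t_e: pd.DataFrame         # zone_id, t_e
    daily_true: pd.DataFrame       # error-free daily positions with zones


def _simulate_bird(rng: np.random.Generator, config: SimConfig,
                   colony: tuple[float, float]) -> np.ndarray:
    """Daily true positions (lon, lat) for one bird over the study period."""
    out = np.empty((config.study_days, 2))
    lon, lat = colony
    # breeding phase: central-place trips within the trip radius
    nb = min(config.breeding_days, config.study_days)
    r = config.trip_radius_km * np.sqrt(rng.uniform(0, 1, nb))
    th = rng.uniform(0, 2 * np.pi, nb)
    for d in range(nb):
        out[d] = _km_offset(colony[0], colony[1],
                            r[d] * np.cos(th[d]), r[d] * np.sin(th[d]))
    # migration phase: waypoint-directed correlated walk, returning home
    waypoints = [(normalize_lon(colony[0] + rng.uniform(-120, 120)),
                  rng.uniform(-55, 5)) for _ in range(config.n_waypoints)]
    waypoints.append(colony)
    lon, lat = out[nb - 1] if nb else colony
    wp = 0
    for d in range(nb, config.study_days):
        tx, ty = waypoints[wp]
        dx = (tx - lon + 180.0) % 360.0 - 180.0
        dy = ty - lat
        dist_km = np.hypot(dx * KM_PER_DEG_LAT * np.cos(np.radians(lat)),
                           dy * KM_PER_DEG_LAT)
        if dist_km < config.step_km and wp < len(waypoints) - 1:
            wp += 1
        step = rng.normal(config.step_km, config.step_km * 0.25)
        step = float(np.clip(step, 0.0, 2.0 * config.step_km))
        if dist_km > 1e-6:
            ux, uy = dx / max(dist_km, 1e-9), dy / max(dist_km, 1e-9)
        else:
            ux = uy = 0.0
        jitter = rng.normal(0.0, config.step_km * 0.3, 2)
        lon, lat = _km_offset(
            lon, lat,
            ux * step * KM_PER_DEG_LAT * np.cos(np.radians(lat)) + jitter[0],
            uy * step * KM_PER_DEG_LAT + jitter[1])
        out[d] = (lon, lat)
    return out


def simulate_tracks(config: SimConfig,
                    world: tuple[ZoneLayer, ZoneLayer],
                    populations: Sequence[BreedingPopulation],
                    ) -> tuple[list[Track], GroundTruth]:
    """Simulate daily tracks and record error-free ground-truth occupancy.

    True zone memberships are recorded before device error; birds drawn into
    the GLS fraction get isotropic Gaussian error added to their *reported*
    positions only. Colonies must sit inside their origin country's zone.
    """
    country_layer, rfmo_layer = world
    rng = np.random.default_rng(config.seed)
    import shapely

    for p in populations:
        z = country_layer.get(p.origin_country)
        if not z.geometry.covers(shapely.points(p.colony_lon, p.colony_lat)):
            raise ValueError(f"colony of {p.population_id!r} lies outside "
                             f"{p.origin_country!r}")

    dates = [config.start_date + dt.timedelta(days=d)
             for d in range(config.study_days)]
    tracks: list[Track] = []
    true_rows = []
    for p in populations:
        for b in range(config.n_birds):
            bird_id = f"{p.population_id}_b{b:03d}"
            device = (Device.GLS if rng.uniform() < config.gls_fraction
                      else Device.GPS)
            true_pos = _simulate_bird(rng, config, (p.colony_lon, p.colony_lat))
            if device is Device.GLS and config.gls_error_km > 0:
                lon_r, lat_r = add_position_error(
                    true_pos[:, 0], true_pos[:, 1], config.gls_error_km, rng)
            else:
                lon_r, lat_r = true_pos[:, 0].copy(), true_pos[:, 1].copy()
            fixes = [Fix(bird_id=bird_id,
                         timestamp=dt.datetime.combine(
                             day, dt.time(12), tzinfo=dt.timezone.utc),
                         lon=float(x), lat=float(y), device=device)
                     for day, x, y in zip(dates, lon_r, lat_r)]
            tracks.append(Track(bird_id=bird_id, species_id=p.species_id,
                                population_id=p.population_id, device=device,
                                fixes=fixes))
            for day, (x, y) in zip(dates, true_pos):
                true_rows.append((bird_id, p.species_id, p.population_id,
                                  device.value, day, day.month, x, y))

    daily_true = pd.DataFrame(true_rows, columns=[
        "bird_id", "species_id", "population_id", "device",
        "local_day", "month", "lon", "lat"])
    assigned_true = assign_frame(daily_true, country_layer, rfmo_layer)
    props = monthly_proportions(assigned_true)
    props = add_population_time(props, populations)
    per_zone, _ = annual_time(props)
    truth = GroundTruth(proportions=props, true_t_e=per_zone,
                        daily_true=assigned_true)
    return tracks, truth


def _estimate_t_e(daily: pd.DataFrame, country_layer: ZoneLayer,
                  populations: Sequence[BreedingPopulation]) -> pd.DataFrame:
    assigned = assign_frame(daily, country_layer)
    props = add_population_time(monthly_proportions(assigned), populations)
    per_zone, _ = annual_time(props)
    return per_zone


def recover_parameters(config: SimConfig,
                       fractions: Sequence[float] = (0.1, 0.5, 1.0),
                       ) -> pd.DataFrame:
    """Estimator-recovery report at several tracked-individual fractions.

    For each fraction, a seeded subset of simulated birds per population is
    treated as "tracked", the full estimation pipeline is run on their
    reported positions, and per-zone relative errors against ground truth
    are reported. With every bird tracked and zero position error the error
    is exactly zero.
    """
    world = make_world(config)
    populations, _ = make_populations(config)
    tracks, truth = simulate_tracks(config, world, populations)
    daily_all = truth.daily_true  # reported == true when gls_fraction == 0
    if config.gls_fraction > 0:
        rows = []
        for t in tracks:
            for f in t.fixes:
                d = f.timestamp.date()
                rows.append((t.bird_id, t.species_id, t.population_id,
                             t.device.value, d, d.month, f.lon, f.lat))
        daily_all = pd.DataFrame(rows, columns=[
            "bird_id", "species_id", "population_id", "device",
            "local_day", "month", "lon", "lat"])

    rng = np.random.default_rng(config.seed + 1)
    true_te = truth.true_t_e.set_index("zone_id")["t_e"]
    out = []
    for frac in fractions:
        sampled_birds: list[str] = []
        for p in populations:
            birds = sorted(daily_all.loc[
                daily_all["population_id"] == p.population_id, "bird_id"].unique())
            n_keep = max(1, int(round(frac * len(birds))))
            keep = rng.choice(len(birds), size=n_keep, replace=False) \
                if n_keep < len(birds) else np.arange(len(birds))
            sampled_birds.extend(birds[i] for i in keep)
        sub = daily_all[daily_all["bird_id"].isin(sampled_birds)]
        est = _estimate_t_e(sub, world[0], populations).set_index("zone_id")["t_e"]
        zones = sorted(set(true_te.index) | set(est.index))
        for z in zones:
            t = float(true_te.get(z, 0.0))
            e = float(est.get(z, 0.0))
            rel = abs(e - t) / t if t > 0 else (np.inf if e > 0 else 0.0)
            out.append((frac, z, t, e, rel))
    return pd.DataFrame(out, columns=["fraction", "zone_id", "true_t_e",
                                      "est_t_e", "rel_error"])


def gls_sensitivity(daily: pd.DataFrame, country_layer: ZoneLayer,
                    populations: Sequence[BreedingPopulation],
                    n_reps: int, error_km: float = 186.0,
                    seed: int = 0) -> pd.DataFrame:
    """Resampling test of zone-importance sensitivity to GLS position error.

    Each replicate adds fresh isotropic Gaussian error (SD ``error_km``) to
    every GLS daily position, reruns assignment, occupancy and richness, and
    reports per-zone deltas against the unperturbed run.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    rng = np.random.default_rng(seed)

    def run(frame: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
        assigned = assign_frame(frame, country_layer)
        props = add_population_time(monthly_proportions(assigned), populations)
        per_zone, _ = annual_time(props)
        te = per_zone.set_index("zone_id")["t_e"]
        rich = pd.Series({r.zone_id: r.total
                          for r in richness_by_zone(assigned, populations,
                                                    country_layer)})
        return te, rich

    te0, rich0 = run(daily)
    gls = (daily["device"] == Device.GLS.value).to_numpy()
    rows = []
    for rep in range(n_reps):
        pert = daily.copy()
        if gls.any() and error_km > 0:
            lon, lat = add_position_error(
                pert.loc[gls, "lon"].to_numpy(),
                pert.loc[gls, "lat"].to_numpy(), error_km, rng)
            pert.loc[gls, "lon"] = lon
            pert.loc[gls, "lat"] = lat
        te, rich = run(pert)
        for z in sorted(set(te0.index) | set(te.index)):
            rows.append((rep, z,
                         float(te0.get(z, 0.0)), float(te.get(z, 0.0)),
                         float(te.get(z, 0.0)) - float(te0.get(z, 0.0)),
                         int(rich0.get(z, 0)), int(rich.get(z, 0)),
                         int(rich.get(z, 0)) - int(rich0.get(z, 0))))
    return pd.DataFrame(rows, columns=[
        "rep", "zone_id", "t_e_base", "t_e", "delta_t_e",
        "richness_base", "richness", "delta_richness"])
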