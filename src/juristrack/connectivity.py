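"""Origin-country ↔ maritime-zone connectivity networks.

Connection strength is built in two steps: per species, the share G_soe of
the species' global annual time spent in a zone that is attributable to
populations breeding under one origin country (bird-years normalised by
12 × N_s); per origin country, strengths G_oe sum those shares over the
breeding species and are expressed in percent. Edges are ranked per origin
and the top k retained (5 for the country layer, 3 for the RFMO layer).
"""

from __future__ import annotations

from typing import Iterable, Optional

import networkx as nx
import pandas as pd

from .data_model import BreedingPopulation, SpeciesInfo

__all__ = [
    "species_origin_share",
    "connection_strength",
    "top_connections",
    "to_networkx",
    "export_network",
]


def species_origin_share(monthly: pd.DataFrame,
                         populations: Iterable[BreedingPopulation],
                         species_info: Iterable[SpeciesInfo]) -> pd.DataFrame:
    """G_soe per (species, origin country, zone).

    ``monthly`` must carry ``t_spme`` (bird-months). Shares sum bird-months
    over all months and all tracked populations of the species breeding in
    the origin country, divide by 12 to get bird-years, and normalise by the
    species' global population size.
    """
    pops = {p.population_id: p for p in populations}
    ns = {s.species_id: s.n_global for s in species_info}
    for sid, n in ns.items():
        if n <= 0:
            raise ValueError(f"species {sid!r} has non-positive global population")

    df = monthly.copy()
    df["origin_country"] = df["population_id"].map(
        lambda p: pops[p].origin_country)
    df["species_id"] = df["population_id"].map(lambda p: pops[p].species_id)
    g = (df.groupby(["species_id", "origin_country", "zone_id"])
         .agg(bird_months=("t_spme", "sum"),
              n_populations=("population_id", "nunique"))
         .reset_index())
    g["g_soe"] = g["bird_months"] / (12.0 * g["species_id"].map(ns))
    return g[["species_id", "origin_country", "zone_id",
              "g_soe", "n_populations", "bird_months"]]


def connection_strength(shares: pd.DataFrame) -> pd.DataFrame:
    """G_oe (percent) per (origin country, zone), summed over species."""
    edges = (shares.groupby(["origin_country", "zone_id"])
             .agg(g_oe=("g_soe", "sum"), n_species=("species_id", "nunique"))
             .reset_index())
    edges["g_oe_percent"] = edges["g_oe"] * 100.0
    return edges[["origin_country", "zone_id", "g_oe_percent", "n_species"]]


def top_connections(edges: pd.DataFrame, k: int = 5,
                    include_self: bool = False) -> pd.DataFrame:
    """Per origin country, the k strongest connections, ranked.

    Self-edges (an origin visiting its own waters) are excluded by default
    so rankings reflect *visited* areas; ties in strength break by species
    count (descending) then zone_id (ascending) for determinism.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    df = edges.copy()
    if not include_self:
        df = df[df["origin_country"] != df["zone_id"]]
    df = df.sort_values(
        by=["origin_country", "g_oe_percent", "n_species", "zone_id"],
        ascending=[True, False, False, True], kind="mergesort")
    df["rank"] = df.groupby("origin_country").cumcount() + 1
    return df[df["rank"] <= k].reset_index(drop=True)


def to_networkx(edges: pd.DataFrame) -> nx.DiGraph:
    """Bipartite-style directed graph: origin country → visited zone."""
    g = nx.DiGraph()
    for _, r in edges.iterrows():
        g.add_node(r["origin_country"], role="origin")
        if r["zone_id"] not in g or g.nodes[r["zone_id"]].get("role") != "origin":
            g.add_node(r["zone_id"], role="visited")
        g.add_edge(r["origin_country"], r["zone_id"],
                   weight=float(r["g_oe_percent"]),
                   n_species=int(r["n_species"]))
    return g


def export_network(edges: pd.DataFrame, edges_path, nodes_path,
                   richness: Optional[dict[str, tuple[int, int]]] = None) -> None:
    """Write deterministic edge and node CSVs for diagramming.

    ``richness`` optionally maps node id → (breeding, visiting) species
    counts for node sizing.
    """
    cols = ["origin_country", "zone_id", "g_oe_percent", "n_species"]
    if "rank" in edges.columns:
        cols.append("rank")
    out = edges[cols].sort_values(cols[:2], kind="mergesort")
    out.to_csv(edges_path, index=False, float_format="%.10g")

    origins = sorted(set(edges["origin_country"]))
    zones = sorted(set(edges["zone_id"]) - set(origins))
    rows = []
    for node in origins + zones:
        role = "origin" if node in set(origins) else "visited"
        br, vi = (richness or {}).get(node, (0, 0))
        rows.append((node, role, br, vi))
    pd.DataFrame(rows, columns=["id", "role", "breeding_richness",
                                "visiting_richness"]).to_csv(nodes_path, index=False)
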