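"""Summary artifacts: standalone zone-importance tables, dataset coverage
summaries, and run-level bookkeeping."""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .data_model import BreedingPopulation

__all__ = [
    "standalone_importance",
    "summarize_dataset",
    "load_reference_coverage",
    "RunReport",
]


def standalone_importance(per_zone_population: pd.DataFrame,
                          populations: Iterable[BreedingPopulation],
                          threshold_pct: float = 0.1) -> pd.DataFrame:
    """Rank zones by total annual time, split into breeding vs visiting birds.

    A zone's "breeding" component is time spent there by populations whose
    origin country owns the zone; everything else is "visiting". Zones
    hosting less than ``threshold_pct`` percent of the grand total are
    collapsed into a final ``Other`` row; listed + Other always conserve the
    grand total exactly.
    """
    origin = {p.population_id: p.origin_country for p in populations}
    df = per_zone_population.copy()
    df["component"] = [
        "breeding" if origin.get(p) == z else "visiting"
        for p, z in zip(df["population_id"], df["zone_id"])]
    tab = (df.pivot_table(index="zone_id", columns="component",
                          values="bird_years", aggfunc="sum", fill_value=0.0)
           .reindex(columns=["breeding", "visiting"], fill_value=0.0)
           .reset_index())
    tab.columns.name = None
    tab["total_bird_years"] = tab["breeding"] + tab["visiting"]
    grand = tab["total_bird_years"].sum()
    tab["pct_total"] = 100.0 * tab["total_bird_years"] / grand if grand else 0.0
    tab = tab.sort_values(["total_bird_years", "zone_id"],
                          ascending=[False, True], kind="mergesort")

    small = tab["pct_total"] < threshold_pct
    listed = tab[~small].reset_index(drop=True)
    if small.any():
        o = tab[small]
        other = pd.DataFrame([{
            "zone_id": "Other",
            "breeding": o["breeding"].sum(),
            "visiting": o["visiting"].sum(),
            "total_bird_years": o["total_bird_years"].sum(),
            "pct_total": o["pct_total"].sum()}])
        listed = pd.concat([listed, other], ignore_index=True)
    return listed


def summarize_dataset(coverage: pd.DataFrame,
                      n_tracking_days: Optional[int] = None) -> dict:
    """Dataset totals plus unweighted across-species means of the coverage
    percentages (population-weighted means are a deliberate non-default)."""
    out = {
        "n_species": int(len(coverage)),
        "total_n_global": float(coverage["n_global"].sum()),
        "total_n_sites": int(coverage["n_sites"].sum()),
        "mean_pct_pop": float(coverage["pct_pop"].mean()),
        "mean_pct_year_known": float(coverage["pct_year_known"].mean()),
        "mean_pct_year_unknown": float(coverage["pct_year_unknown"].mean()),
    }
    if "n_birds" in coverage.columns and coverage["n_birds"].notna().all():
        out["total_n_birds"] = int(coverage["n_birds"].sum())
    if n_tracking_days is not None:
        out["total_tracking_days"] = int(n_tracking_days)
    return out


def load_reference_coverage() -> pd.DataFrame:
    """Reference tracking-coverage table for the 39 study species.

    Serves as a fixture for coverage summaries: global population size,
    tracked sites and birds, and the percentage-coverage columns.
    """
    ref = importlib.resources.files("juristrack.data") / "reference_coverage.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


@dataclass
class RunReport:
    """Stage-by-stage accounting for one pipeline run."""

    config: dict = field(default_factory=dict)
    variant_id: str = "baseline"
    version: str = ""
    stages: list[dict] = field(default_factory=list)

    def add_stage(self, name: str, n_in: int, n_out: int,
                  n_rejected: int = 0, **extra) -> None:
        if n_in != n_out + n_rejected:
            raise ValueError(
                f"stage {name!r}: counts do not reconcile "
                f"({n_in} != {n_out} + {n_rejected})")
        self.stages.append({"stage": name, "n_in": n_in, "n_out": n_out,
                            "n_rejected": n_rejected, **extra})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages)
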