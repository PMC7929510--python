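# juristrack

Population-weighted estimation of the year-round importance of national
jurisdictions, the high seas, and RFMO (regional fisheries management
organization) competence areas to breeding populations of wide-ranging
seabirds, from individual tracking data.

The pipeline:

1. **Ingest & preprocess** — validate tracking tables (GLS/PTT/GPS), reduce
   each track to one fix per local solar day (nearest local noon), truncate
   to the 365 days after device attachment, apply configurable GLS filters
   (equinox window, daily displacement), and mask population-months with
   fewer than 10 unique tracking days (optionally ≥5 individuals).
2. **Zone assignment** — build an exhaustive country/high-seas partition
   (land ∪ EEZ unions per sovereign, dependencies aggregated, disputed areas
   kept as named zones, an Antarctic zone south of 60°S) plus an overlapping
   RFMO overlay clipped to the high seas, and assign every daily position.
3. **Occupancy** — monthly per-individual zone proportions averaged per
   population, scaled by breeding population size N_p to bird-months
   (T_spme), summed over tracked months and divided by 12 to bird-years
   (T_e). Untracked months contribute zero (conservative). Zone species
   richness is split into breeding / visiting / both categories, with an
   underestimation audit against known breeding-country lists, and surfaces
   can be binned on a global quasi-hexagonal equal-area grid (mean
   cell-center spacing 495 ± 30 km).
4. **Connectivity** — per-species origin-country shares of annual time per
   zone (G_soe, normalized by global population size N_s), summed to
   percent connection strengths per origin country (G_oe), ranked top-k
   edge lists (k = 5 country layer, k = 3 RFMO layer).
5. **Synthetic data** — deterministic toy worlds, populations, and
   movement simulations with known ground truth, estimator-recovery
   reports, and a GLS position-error sensitivity resampling procedure
   (isotropic Gaussian, default SD 186 km).

## CLI

```sh
juristrack simulate --out world/                       # toy world + tracks
juristrack preprocess --tracks world/tracks.csv --out prep/ --min-days 10
juristrack assign --daily prep/daily.csv \
    --zones world/zones_country.geojson --rfmo world/zones_rfmo.geojson \
    --out prep/assignments.csv
juristrack occupancy --assignments prep/assignments.csv \
    --populations world/populations.csv --species world/species.csv \
    --mask prep/representativeness.csv --zones world/zones_country.geojson \
    --out occ/
juristrack connect --occupancy occ/occupancy_country.csv \
    --populations world/populations.csv --species world/species.csv \
    --top-k 5 --out net/
juristrack report --annual-by-population occ/annual_country_by_population.csv \
    --populations world/populations.csv --species world/species.csv \
    --mask prep/representativeness.csv --out report.md
```

Global options: `--config <yaml>` (sections `io`, `filters`, `zones`,
`grid`, `connectivity`, `simulation`), `--seed`, `--log-level`.

Formats: tracking tables are UTF-8 CSV with ISO-8601 UTC timestamps and a
configurable column mapping; zones are GeoJSON feature collections with
`zone_id`, `layer`, `sovereign`, `claimants`, `disputed` properties
(antimeridian-crossing polygons are split at read time; longitudes are
normalized to [-180, 180)).

## Notes

- The country layer is an exhaustive partition: every daily position gets
  exactly one country-layer zone (high seas is the complement/fallback).
  RFMO competence areas overlap, so high-seas days may count toward several
  RFMOs and per-RFMO totals are deliberately not additive.
- The global grid is a spherical-Fibonacci Voronoi lattice; cell areas are
  equal to within 1% relative SD, with a handful of flagged irregular cells
  at the poles and at the lattice's pentagon/heptagon sites.
- Disputed zones hosting tracked colonies trigger paired analysis variants
  with sovereignty assigned alternately to each claimant.
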