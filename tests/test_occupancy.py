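import datetime as dt
import itertools

import numpy as np
import pandas as pd
import pytest

from juristrack.data_model import (
    HIGH_SEAS_ID,
    BreedingPopulation,
    SpeciesInfo,
)
from juristrack.occupancy import (
    add_population_time,
    annual_time,
    coverage_table,
    grid_aggregate,
    monthly_proportions,
    rfmo_monthly_proportions,
    richness_by_zone,
    richness_underestimation,
)


def assignment_frame(entries):
    """entries: (bird, population, species, month, day, zone[, rfmos])."""
    rows = []
    for e in entries:
        bird, pop, sp, month, day, zone = e[:6]
        rfmos = e[6] if len(e) > 6 else frozenset()
        rows.append((bird, sp, pop, "GPS", dt.date(2017, month, day),
                     month, 0.0, 0.0, zone, rfmos))
    return pd.DataFrame(rows, columns=[
        "bird_id", "species_id", "population_id", "device", "local_day",
        "month", "lon", "lat", "country_zone", "rfmo_zones"])


def pop(pid, origin="A", species="s1", n_adults=100.0, lon=0.0, lat=0.0):
    return BreedingPopulation(population_id=pid, species_id=species,
                              island_group=pid, origin_country=origin,
                              colony_lon=lon, colony_lat=lat, n_adults=n_adults)


class TestMonthlyProportions:
    def test_ten_of_thirtyone_january_days(self):
        # one bird, 31 tracked January days, 10 in the high seas
        entries = [("b1", "p", "s1", 1, d, HIGH_SEAS_ID) for d in range(1, 11)]
        entries += [("b1", "p", "s1", 1, d, "A") for d in range(11, 32)]
        m = monthly_proportions(assignment_frame(entries))
        hs = m.loc[m.zone_id == HIGH_SEAS_ID, "mean_prop"].item()
        assert hs == pytest.approx(10 / 31)
        assert round(100 * hs) == 32

    def test_single_zone_gives_one(self):
        m = monthly_proportions(assignment_frame(
            [("b1", "p", "s1", 2, d, "A") for d in range(1, 6)]))
        assert m["mean_prop"].tolist() == [1.0]

    def test_mean_over_individuals(self):
        # bird1: 1/5 days in HS (0.2); bird2: 2/5 (0.4) -> mean 0.3
        entries = [("b1", "p", "s1", 1, 1, HIGH_SEAS_ID)]
        entries += [("b1", "p", "s1", 1, d, "A") for d in range(2, 6)]
        entries += [("b2", "p", "s1", 1, d, HIGH_SEAS_ID) for d in (1, 2)]
        entries += [("b2", "p", "s1", 1, d, "A") for d in range(3, 6)]
        m = monthly_proportions(assignment_frame(entries))
        hs = m.loc[m.zone_id == HIGH_SEAS_ID, "mean_prop"].item()
        assert hs == pytest.approx(0.3)
        assert m["n_individuals"].unique().tolist() == [2]

    def test_proportions_sum_to_one_per_population_month(self):
        rng = np.random.default_rng(0)
        zones = ["A", "B", HIGH_SEAS_ID]
        entries = [(f"b{b}", "p", "s1", month, day,
                    zones[rng.integers(0, 3)])
                   for b in range(4) for month in (1, 2)
                   for day in range(1, 20)]
        m = monthly_proportions(assignment_frame(entries))
        sums = m.groupby(["population_id", "month"])["mean_prop"].sum()
        assert np.allclose(sums, 1.0)

    def test_mask_drops_population_months(self):
        entries = [("b1", "p", "s1", 1, d, "A") for d in range(1, 12)]
        entries += [("b1", "p", "s1", 2, 1, "A")]
        mask = pd.DataFrame({"population_id": ["p", "p"], "month": [1, 2],
                             "retained": [True, False]})
        m = monthly_proportions(assignment_frame(entries), mask)
        assert set(m["month"]) == {1}


class TestPopulationTime:
    def test_half_time_scales_by_np(self):
        m = pd.DataFrame({"population_id": ["p"], "month": [1],
                          "zone_id": ["A"], "mean_prop": [0.5],
                          "n_individuals": [3]})
        out = add_population_time(m, [pop("p", n_adults=100)])
        assert out["t_spme"].item() == 50.0

    def test_uses_unrounded_mean(self):
        # a mean of 21/62 must not be rounded to 0.34 before scaling
        m = pd.DataFrame({"population_id": ["p"], "month": [1],
                          "zone_id": ["A"], "mean_prop": [21 / 62],
                          "n_individuals": [2]})
        out = add_population_time(m, [pop("p", n_adults=1000)])
        assert out["t_spme"].item() == pytest.approx(1000 * 21 / 62)

    def test_zero_mean_zero_time(self):
        m = pd.DataFrame({"population_id": ["p"], "month": [1],
                          "zone_id": ["A"], "mean_prop": [0.0],
                          "n_individuals": [1]})
        assert add_population_time(m, [pop("p")])["t_spme"].item() == 0.0

    def test_unknown_population_is_error(self):
        m = pd.DataFrame({"population_id": ["q"], "month": [1],
                          "zone_id": ["A"], "mean_prop": [1.0],
                          "n_individuals": [1]})
        with pytest.raises(KeyError, match="q"):
            add_population_time(m, [pop("p")])


def monthly_table(rows):
    return pd.DataFrame(rows, columns=["population_id", "month", "zone_id",
                                       "mean_prop", "n_individuals", "t_spme"])


class TestAnnualTime:
    def test_full_year_half_time(self):
        rows = [("p", m, "A", 0.5, 2, 500.0) for m in range(1, 13)]
        per_zone, _ = annual_time(monthly_table(rows))
        assert per_zone.set_index("zone_id").loc["A", "t_e"] == pytest.approx(500.0)

    def test_divides_by_twelve_not_months_tracked(self):
        rows = [("p", m, "A", 1.0, 2, 1200.0) for m in range(1, 7)]
        per_zone, _ = annual_time(monthly_table(rows))
        assert per_zone.set_index("zone_id").loc["A", "t_e"] == pytest.approx(600.0)

    def test_three_population_birdmonth_aggregation(self):
        # frozen per-population annual bird-month sums; the division by 12
        # happens once, on the pooled total
        sums = {"madeira": 115_844.0, "azores": 1_988_600.0, "berlengas": 4_771.0}
        rows = []
        for p, total in sums.items():
            for m in range(1, 12):
                rows.append((p, m, HIGH_SEAS_ID, 0.1, 2, total / 11.0))
        per_zone, per_pop = annual_time(monthly_table(rows))
        assert per_pop["bird_months"].sum() == pytest.approx(2_109_215.0)
        t_e = per_zone.set_index("zone_id").loc[HIGH_SEAS_ID, "t_e"]
        assert round(t_e) == 175_768

    def test_conservation_against_brute_force(self):
        rng = np.random.default_rng(1)
        rows = []
        months_by_pop = {"p1": range(1, 13), "p2": range(3, 9)}
        n_p = {"p1": 1000.0, "p2": 500.0}
        for p, months in months_by_pop.items():
            for m in months:
                props = rng.dirichlet(np.ones(3))
                for z, pr in zip(["A", "B", HIGH_SEAS_ID], props):
                    rows.append((p, m, z, pr, 2, pr * n_p[p]))
        per_zone, _ = annual_time(monthly_table(rows))
        want = sum(n_p[p] * len(list(months_by_pop[p])) / 12.0
                   for p in months_by_pop)
        assert per_zone["t_e"].sum() == pytest.approx(want, rel=1e-12)

    def test_adding_a_month_never_decreases_totals(self):
        rows = [("p", m, "A", 1.0, 1, 100.0) for m in range(1, 6)]
        base, _ = annual_time(monthly_table(rows))
        more, _ = annual_time(monthly_table(rows + [("p", 6, "A", 1.0, 1, 100.0)]))
        assert more["t_e"].sum() >= base["t_e"].sum()


class TestRfmoProportions:
    def test_high_seas_days_only_with_full_denominator(self):
        entries = [("b1", "p", "s1", 1, 1, HIGH_SEAS_ID, frozenset({"r1", "r2"})),
                   ("b1", "p", "s1", 1, 2, HIGH_SEAS_ID, frozenset({"r1"})),
                   ("b1", "p", "s1", 1, 3, "A"),
                   ("b1", "p", "s1", 1, 4, "A")]
        m = rfmo_monthly_proportions(assignment_frame(entries))
        by_zone = m.set_index("zone_id")["mean_prop"]
        assert by_zone["r1"] == pytest.approx(2 / 4)   # both HS days, of 4 total
        assert by_zone["r2"] == pytest.approx(1 / 4)

    def test_empty_when_no_high_seas(self):
        m = rfmo_monthly_proportions(assignment_frame(
            [("b1", "p", "s1", 1, 1, "A")]))
        assert m.empty


class TestRichness:
    def make_layer(self):
        from shapely.geometry import box
        from juristrack.zones import build_country_layer
        eez = [{"territory": "ta", "geometry": box(-30, -10, -10, 10)},
               {"territory": "tb", "geometry": box(10, -10, 30, 10)}]
        return build_country_layer(eez, territory_map={"ta": "A", "tb": "B"})

    def test_breeding_only_species(self):
        layer = self.make_layer()
        pops = [pop("p1", origin="A", species="s1")]
        assigned = assignment_frame([("b1", "p1", "s1", 1, 1, "A")])
        recs = {r.zone_id: r for r in richness_by_zone(assigned, pops, layer)}
        assert recs["A"].breeding_only == {"s1"}
        assert recs["B"].breeding_only == frozenset()
        assert recs["B"].visiting_only == frozenset()

    def test_both_category(self):
        layer = self.make_layer()
        pops = [pop("p1", origin="A", species="s1"),
                pop("p2", origin="B", species="s1")]
        assigned = assignment_frame([("b1", "p1", "s1", 1, 1, "A"),
                                     ("b2", "p2", "s1", 1, 1, "A")])
        recs = {r.zone_id: r for r in richness_by_zone(assigned, pops, layer)}
        assert recs["A"].both == {"s1"}
        assert recs["A"].breeding_only == frozenset()

    def test_high_seas_all_visiting(self):
        layer = self.make_layer()
        pops = [pop("p1", origin="A", species="s1")]
        assigned = assignment_frame([("b1", "p1", "s1", 1, 1, HIGH_SEAS_ID)])
        recs = {r.zone_id: r for r in richness_by_zone(assigned, pops, layer)}
        assert recs[HIGH_SEAS_ID].visiting_only == {"s1"}

    def test_categories_disjoint(self):
        layer = self.make_layer()
        pops = [pop("p1", origin="A", species="s1"),
                pop("p2", origin="B", species="s1"),
                pop("p3", origin="A", species="s2")]
        assigned = assignment_frame([("b1", "p1", "s1", 1, 1, "A"),
                                     ("b2", "p2", "s1", 1, 1, "A"),
                                     ("b3", "p3", "s2", 1, 1, "B"),
                                     ("b3", "p3", "s2", 1, 2, HIGH_SEAS_ID)])
        for r in richness_by_zone(assigned, pops, layer):
            for a, b in itertools.combinations(
                    [r.breeding_only, r.visiting_only, r.both], 2):
                assert not (a & b)


class TestRichnessUnderestimation:
    def rec(self, zone, breeding):
        from juristrack.occupancy import RichnessRecord
        return RichnessRecord(zone_id=zone, breeding_only=frozenset(breeding),
                              visiting_only=frozenset(), both=frozenset())

    def test_simple_delta(self):
        spp = [SpeciesInfo(species_id=f"s{i}", n_global=10,
                           known_breeding_countries=frozenset({"A"}))
               for i in range(3)]
        df, mean, _ = richness_underestimation(
            [self.rec("A", {"s0", "s1"})], spp)
        assert df.loc[0, "delta"] == 1

    def test_all_tracked_zero_delta(self):
        spp = [SpeciesInfo(species_id="s0", n_global=10,
                           known_breeding_countries=frozenset({"A"}))]
        df, mean, sd = richness_underestimation([self.rec("A", {"s0"})], spp)
        assert mean == 0.0

    def test_tracked_exceeding_known_is_error(self):
        spp = [SpeciesInfo(species_id="s0", n_global=10,
                           known_breeding_countries=frozenset({"B"}))]
        with pytest.raises(ValueError, match="not in known"):
            richness_underestimation([self.rec("B", {"s0", "sX"})], spp)

    def test_22_country_fixture_mean_one(self):
        # constructed fixture: 22 countries, alternating fully tracked
        # (delta 0) and fully missed (delta 2) -> brute-force mean delta 1.0
        spp, recs = [], []
        deltas = []
        for i in range(22):
            c = f"c{i:02d}"
            known = {f"{c}_s0", f"{c}_s1"}
            tracked = set(known) if i % 2 == 0 else set()
            deltas.append(len(known) - len(tracked))
            for s in known:
                spp.append(SpeciesInfo(species_id=s, n_global=10,
                                       known_breeding_countries=frozenset({c})))
            recs.append(self.rec(c, tracked))
        df, mean, sd = richness_underestimation(recs, spp)
        assert len(df) == 22
        assert mean == pytest.approx(np.mean(deltas)) == pytest.approx(1.0)
        assert sd == pytest.approx(np.std(deltas, ddof=1))


class TestGridAggregate:
    def test_two_species_richness(self):
        from juristrack.grid import HexGrid
        grid = HexGrid(64)
        daily = assignment_frame([("b1", "p1", "s1", 1, 1, "A"),
                                  ("b2", "p2", "s2", 1, 1, "A")])
        surf = grid_aggregate(daily, grid, statistic="richness")
        assert surf.values["richness"].max() == 2
        assert surf.values["richness"].sum() == 2

    def test_time_conservation_single_cell(self):
        from juristrack.grid import HexGrid
        grid = HexGrid(64)
        entries = [("b1", "p1", "s1", m, d, "A")
                   for m in range(1, 13) for d in range(1, 11)]
        daily = assignment_frame(entries)
        surf = grid_aggregate(daily, grid, populations=[pop("p1", n_adults=1000)],
                              statistic="time")
        vals = surf.values["bird_years"]
        assert vals.sum() == pytest.approx(1000.0)
        assert (vals > 0).sum() == 1   # all fixes at one point -> one cell

    def test_monthly_variant_emits_per_month(self):
        from juristrack.grid import HexGrid
        grid = HexGrid(64)
        daily = assignment_frame([("b1", "p1", "s1", 1, 1, "A"),
                                  ("b1", "p1", "s1", 2, 1, "A")])
        surf = grid_aggregate(daily, grid, statistic="richness", monthly=True)
        assert set(surf.values) == {"richness_m01", "richness_m02"}


class TestCoverageTable:
    def species(self, n_global, sid="s1"):
        return SpeciesInfo(species_id=sid, n_global=n_global,
                           known_breeding_countries=frozenset({"A"}))

    def test_fully_tracked_species(self):
        cov = coverage_table([pop("p1", n_adults=90.0)],
                             [self.species(90.0)],
                             pd.Series({"p1": 12}))
        row = cov.iloc[0]
        assert (row.pct_pop, row.pct_year_known, row.pct_year_unknown) == (100, 100, 0)

    def test_partial_year_row(self):
        # 78% of the population tracked for 8 of 12 months -> 52% known
        cov = coverage_table([pop("p1", n_adults=2028.0)],
                             [self.species(2600.0)],
                             pd.Series({"p1": 8}))
        row = cov.iloc[0]
        assert row.pct_pop == pytest.approx(78.0)
        assert row.pct_year_known == pytest.approx(52.0)
        assert row.pct_year_unknown == pytest.approx(48.0)

    def test_untracked_species(self):
        cov = coverage_table([], [self.species(100.0)], pd.Series(dtype=float))
        row = cov.iloc[0]
        assert (row.pct_pop, row.pct_year_known, row.pct_year_unknown) == (0, 0, 100)

    def test_known_bounded_by_pop(self):
        cov = coverage_table(
            [pop("p1", n_adults=500.0)], [self.species(1000.0)],
            pd.Series({"p1": 7}))
        row = cov.iloc[0]
        assert row.pct_year_known <= row.pct_pop <= 100.0

    def test_adding_month_monotone(self):
        base = coverage_table([pop("p1", n_adults=500.0)], [self.species(1000.0)],
                              pd.Series({"p1": 7})).iloc[0].pct_year_known
        more = coverage_table([pop("p1", n_adults=500.0)], [self.species(1000.0)],
                              pd.Series({"p1": 8})).iloc[0].pct_year_known
        assert more >= base
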