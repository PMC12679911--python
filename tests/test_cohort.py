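import numpy as np
import pandas as pd
import pytest

from herdvigor.cohort import (build_cohort_table, first_calving_wean_rate,
                              first_cycle_linkage, grandcalves_per_sire,
                              pct_remaining, per_sire_first_cycle_shares,
                              total_kg_weaned_per_sire)
from herdvigor.prolificacy import SireStratum


class TestDerivedCells:
    def test_pct_remaining_final_year(self):
        # 29 of 74 retained 2015-born heifers still calving in 2020
        assert pct_remaining(29, 74) == 39.2
        assert pct_remaining(51, 86) == 59.3
        assert pct_remaining(7, 10) == 70.0
        assert pct_remaining(6, 7, ndigits=0) == 86.0

    def test_grandcalves_per_sire_one_decimal(self):
        assert grandcalves_per_sire(16, 4) == 4.0
        assert grandcalves_per_sire(27, 4) == 6.8  # 6.75 rounds half-up
        assert grandcalves_per_sire(81, 8) == 10.1

    def test_total_kg_uses_rounded_calf_average(self):
        assert total_kg_weaned_per_sire(205.94, 4.0) == 823.76
        assert total_kg_weaned_per_sire(196.63, 6.8) == 1337.08
        # the unrounded variant differs for the 6.75-average row
        assert total_kg_weaned_per_sire(
            196.63, 6.75, use_rounded_average=False) == 1327.25

    def test_first_calving_wean_rates(self):
        assert first_calving_wean_rate(54, 74) == 73
        assert first_calving_wean_rate(68, 86) == 79
        assert first_calving_wean_rate(0, 10) == 0

    def test_zero_retained_is_an_error(self):
        with pytest.raises(ZeroDivisionError):
            pct_remaining(1, 0)
        with pytest.raises(ZeroDivisionError):
            first_calving_wean_rate(1, 0)


def _fit_pipeline(sim):
    from herdvigor.config import RunConfig
    from herdvigor.cycles import assign_cycles
    from herdvigor.parentage import apply_assignments, verify_parentage
    from herdvigor.prolificacy import bpi_table, stratify_sires

    par = verify_parentage(sim.herd, sim.panel, RunConfig())
    herd = apply_assignments(sim.herd, par)
    cyc = assign_cycles(herd)
    records = bpi_table(par, herd, cyc)
    strata = stratify_sires(records)
    return herd, cyc, records, strata


@pytest.fixture(scope="module")
def fitted(sim):
    return _fit_pipeline(sim)


class TestCohortTable:
    def test_calves_by_year_conserved_in_total_row(self, fitted):
        herd, _, _, strata = fitted
        years = sorted(int(y) for y in herd.calves["year"].dropna().unique())
        table = build_cohort_table(herd, strata, [years[0]])
        year_cols = [c for c in table.columns if c.startswith("calves_")]
        strata_rows = table[table["stratum"] != "Total"]
        total_row = table[table["stratum"] == "Total"].iloc[0]
        for col in year_cols:
            assert strata_rows[col].sum() == total_row[col]

    def test_every_grandcalf_dam_is_a_retained_daughter(self, fitted):
        herd, _, _, strata = fitted
        years = sorted(int(y) for y in herd.calves["year"].dropna().unique())
        birth_year = years[0]
        calves = herd.calves
        for stratum in strata:
            daughters = calves[(calves["year"] == birth_year)
                               & (calves["sex"] == "F")
                               & calves["assigned_sire_id"].isin(stratum.members)]
            rids = set(daughters[daughters["retained"]]["animal_id"])
            grand = calves[calves["dam_id"].isin(rids)]
            assert set(grand["dam_id"]) <= rids

    def test_zero_daughter_stratum_gives_zero_cells(self, fitted):
        herd, _, _, _ = fitted
        ghost = SireStratum("Top25", 2.0, ["no-such-sire"])
        years = sorted(int(y) for y in herd.calves["year"].dropna().unique())
        table = build_cohort_table(herd, [ghost], [years[0]])
        row = table[table["stratum"] == "Top25"].iloc[0]
        assert row["n_daughters_retained"] == 0
        assert row["total_calves_weaned"] == 0
        assert row["total_kg_weaned_per_sire"] == 0.0

    def test_derived_cells_satisfy_their_definitions(self, fitted):
        herd, _, _, strata = fitted
        years = sorted(int(y) for y in herd.calves["year"].dropna().unique())
        table = build_cohort_table(herd, strata, [years[0]])
        for _, r in table[table["stratum"] != "Total"].iterrows():
            if r["n_sires"] and r["total_calves_weaned"]:
                assert r["avg_grandcalves_per_sire"] == grandcalves_per_sire(
                    r["total_calves_weaned"], r["n_sires"])
                assert r["total_kg_weaned_per_sire"] == total_kg_weaned_per_sire(
                    r["avg_ww_per_calf"], r["avg_grandcalves_per_sire"])


class TestFirstCycleLinkage:
    def _strata(self, sires):
        return [SireStratum("Top25", 1.8, sires)]

    def test_collinear_points_give_unit_r_squared(self):
        df = pd.DataFrame({
            "sire_id": ["a", "b", "c", "d"],
            "pct_daughters_cycle1": [40.0, 55.0, 70.0, 85.0],
            "pct_grandcalves_cycle1": [30.0, 45.0, 60.0, 75.0],
        })
        out = first_cycle_linkage(df, self._strata(["a", "b", "c", "d"]))
        assert out.iloc[0]["r_squared"] == pytest.approx(1.0)

    def test_flat_response_gives_zero_r_squared(self):
        df = pd.DataFrame({
            "sire_id": ["a", "b", "c", "d"],
            "pct_daughters_cycle1": [40.0, 55.0, 70.0, 85.0],
            "pct_grandcalves_cycle1": [50.0, 50.0, 50.0, 50.0],
        })
        out = first_cycle_linkage(df, self._strata(["a", "b", "c", "d"]))
        assert out.iloc[0]["r_squared"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_computed_r_squared_on_fixture(self):
        x = np.array([10.0, 30.0, 50.0, 70.0, 90.0])
        y = np.array([20.0, 35.0, 40.0, 70.0, 80.0])
        df = pd.DataFrame({"sire_id": list("abcde"),
                           "pct_daughters_cycle1": x,
                           "pct_grandcalves_cycle1": y})
        out = first_cycle_linkage(df, self._strata(list("abcde")))
        slope, intercept = np.polyfit(x, y, 1)
        ss_res = ((y - (slope * x + intercept)) ** 2).sum()
        ss_tot = ((y - y.mean()) ** 2).sum()
        assert out.iloc[0]["r_squared"] == pytest.approx(1 - ss_res / ss_tot)

    def test_too_few_sires_flagged_undefined(self):
        df = pd.DataFrame({"sire_id": ["a", "b"],
                           "pct_daughters_cycle1": [40.0, 60.0],
                           "pct_grandcalves_cycle1": [40.0, 60.0]})
        out = first_cycle_linkage(df, self._strata(["a", "b"]))
        assert bool(out.iloc[0]["undefined"])

    def test_per_sire_shares_computable_from_simulation(self, fitted):
        herd, cyc, _, _ = fitted
        years = sorted(int(y) for y in herd.calves["year"].dropna().unique())
        shares = per_sire_first_cycle_shares(herd, cyc, years[:2])
        assert not shares.empty
        assert shares["pct_daughters_cycle1"].between(0, 100).all()
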