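import numpy as np
import pandas as pd
import pytest

from herdvigor._util import round_half_up
from herdvigor.prolificacy import (age_summary, bpi, bpi_first_cycle,
                                   bpi_range_table, bpi_table, repeatability,
                                   strata_frame, stratify_sires)


class TestBPIFormula:
    @pytest.mark.parametrize("n,N,m,printed,ndigits", [
        (10, 126, 5, 0.4, 1),    # minimum of a 5-sire mature-cow group
        (49, 113, 8, 3.47, 2),   # study-wide maximum
        (1, 136, 6, 0.04, 2),    # study-wide minimum
        (51, 121, 6, 2.5, 1),
        (4, 121, 6, 0.2, 1),
        (38, 136, 6, 1.7, 1),
    ])
    def test_published_cells_reproduced(self, n, N, m, printed, ndigits):
        assert round_half_up(bpi(n, N, m), ndigits) == printed

    def test_full_precision_retained(self):
        assert bpi(10, 126, 5) == pytest.approx(10 * 5 / 126)

    def test_equal_share_scores_one(self):
        assert bpi(20, 100, 5) == 1.0

    def test_undefined_without_calves_or_sires(self):
        with pytest.raises(ZeroDivisionError):
            bpi(0, 0, 5)
        with pytest.raises(ZeroDivisionError):
            bpi(1, 10, 0)

    def test_n_bounded_by_total(self):
        with pytest.raises(ValueError):
            bpi(11, 10, 2)

    def test_first_cycle_substitution(self):
        assert bpi_first_cycle(5, 20, 4) == 1.0
        # when every calf is first-cycle the substitution is the identity
        assert bpi_first_cycle(7, 35, 5) == bpi(7, 35, 5)

    def test_scale_invariance(self):
        assert bpi(6, 60, 4) == bpi(12, 120, 4)


def _records(values, sire_prefix="s", **extra):
    rows = []
    for i, v in enumerate(values):
        rows.append({"sire_id": f"{sire_prefix}{i:02d}", "group": 1,
                     "year": 2014, "n": 1, "N": len(values),
                     "m": len(values), "bpi": v, "sire_age": 2, **extra})
    return pd.DataFrame(rows)


class TestBPITable:
    def test_group_year_sum_is_sire_count(self, sim):
        from herdvigor.config import RunConfig
        from herdvigor.parentage import verify_parentage

        par = verify_parentage(sim.herd, sim.panel, RunConfig())
        records = bpi_table(par, sim.herd)
        for (g, y), gy in records.groupby(["group", "year"]):
            assert gy["bpi"].sum() == pytest.approx(gy["m"].iloc[0])

    def test_range_table_from_constructed_group(self, tiny_herd):
        # a 6-sire group-year with calf counts (1, 38, 30, 30, 20, 17)
        counts = {"s0": 1, "s1": 38, "s2": 30, "s3": 30, "s4": 20, "s5": 17}
        roster = pd.DataFrame({"sire_id": list(counts), "group": 2,
                               "year": 2015})
        cols = tiny_herd.animals.columns
        new_rows, calf_rows = [], []
        for s in counts:
            new_rows.append([s, "M", pd.Timestamp("2012-04-01").date(),
                             None, None, None, None, None, 40.0, None,
                             False, None])
        k = 0
        for s, cnt in counts.items():
            for _ in range(cnt):
                cid = f"x{k}"
                k += 1
                new_rows.append([cid, "M", pd.Timestamp("2016-04-05").date(),
                                 None, None, s, 2, 2015, 38.0, None, False,
                                 None])
                calf_rows.append({"calf_id": cid, "assigned_sire_id": s})
        from herdvigor.herdbook import HerdBook

        animals = pd.concat(
            [tiny_herd.animals, pd.DataFrame(new_rows, columns=cols)],
            ignore_index=True)
        herd = HerdBook(animals, pd.concat(
            [tiny_herd.sire_groups, roster], ignore_index=True))
        records = bpi_table(pd.DataFrame(calf_rows), herd)
        table = bpi_range_table(records)
        row = table[(table["group"] == 2) & (table["year"] == 2015)].iloc[0]
        assert row["total_calves"] == 136
        assert round_half_up(row["min_bpi"], 2) == 0.04
        assert round_half_up(row["max_bpi"], 1) == 1.7

    def test_zero_calf_sire_flagged_not_silent(self, sim):
        from herdvigor.config import RunConfig
        from herdvigor.parentage import verify_parentage

        par = verify_parentage(sim.herd, sim.panel, RunConfig())
        records = bpi_table(par, sim.herd)
        zero = records[records["n"] == 0]
        assert (zero["bpi"] == 0).all()  # bpi = 0 iff n = 0
        assert (records.loc[records["bpi"] == 0, "n"] == 0).all()


class TestStratification:
    def test_equal_bpi_eight_sires_split_2_4_2_by_id(self):
        strata = stratify_sires(_records([1.0] * 8))
        sizes = {s.label: len(s.members) for s in strata}
        assert sizes == {"Bottom25": 2, "Average50": 4, "Top25": 2}
        assert strata[0].members == ["s00", "s01"]  # id tie-break
        assert strata[2].members == ["s06", "s07"]

    def test_membership_partitions_sires(self):
        df = _records(np.linspace(0.1, 2.0, 11))
        strata = stratify_sires(df)
        members = [m for s in strata for m in s.members]
        assert sorted(members) == sorted(df["sire_id"])
        assert len(members) == len(set(members))

    def test_fewer_than_four_collapses_to_single_stratum(self):
        strata = stratify_sires(_records([0.5, 1.5, 1.0]))
        assert len(strata) == 1
        assert len(strata[0].members) == 3

    def test_stratum_averages_ordered(self):
        strata = stratify_sires(_records(np.linspace(0.1, 2.0, 16)))
        avgs = [s.avg_bpi for s in strata]
        assert avgs == sorted(avgs)


def _two_year_records(year1, year2):
    rows = []
    for i, (a, b) in enumerate(zip(year1, year2)):
        rows.append({"sire_id": f"s{i}", "group": 1, "year": 2014, "n": 5,
                     "N": 50, "m": 5, "bpi": a, "sire_age": 1})
        rows.append({"sire_id": f"s{i}", "group": 1, "year": 2015, "n": 5,
                     "N": 50, "m": 5, "bpi": b, "sire_age": 2})
    return pd.DataFrame(rows)


class TestRepeatability:
    def test_preserved_ranks_give_unit_correlation(self):
        rep = repeatability(_two_year_records([0.2, 0.8, 1.4, 2.0],
                                              [0.3, 0.9, 1.5, 2.1]))
        assert rep.iloc[0]["rho"] == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        rep = repeatability(_two_year_records([0.2, 0.8, 1.4, 2.0],
                                              [2.1, 1.5, 0.9, 0.3]))
        assert rep.iloc[0]["rho"] == pytest.approx(-1.0)

    def test_matches_definitional_rank_formula_on_fixture(self):
        y1 = [0.3, 1.1, 0.7, 1.9, 0.5]
        y2 = [0.6, 1.4, 1.0, 1.2, 0.2]
        rep = repeatability(_two_year_records(y1, y2))
        # no ties: rho = 1 - 6*sum(d^2)/(n(n^2-1))
        r1 = pd.Series(y1).rank()
        r2 = pd.Series(y2).rank()
        d2 = ((r1 - r2) ** 2).sum()
        expected = 1 - 6 * d2 / (5 * 24)
        assert rep.iloc[0]["rho"] == pytest.approx(expected)

    def test_permutation_p_small_for_perfect_agreement(self):
        y = list(np.linspace(0.2, 2.0, 8))
        rep = repeatability(_two_year_records(y, y))
        assert rep.iloc[0]["p_value"] < 0.01

    def test_too_few_pairs_flagged(self):
        rep = repeatability(_two_year_records([1.0, 2.0], [1.0, 2.0]))
        assert bool(rep.iloc[0]["undefined"])


class TestAgeSummary:
    def test_single_yearling_record(self):
        df = _records([0.5])
        df["sire_age"] = 1
        out = age_summary(df)
        row = out[out["age_class"] == "1"].iloc[0]
        assert row["mean"] == 0.5
        assert row["sd"] == 0.0

    def test_classes_partition_records(self):
        df = _records(np.linspace(0.2, 2.0, 9))
        df["sire_age"] = [1, 1, 2, 2, 3, 4, 5, 6, 3]
        out = age_summary(df)
        assert out["n"].sum() == len(df)
        assert set(out["age_class"]) == {"1", "2", ">=3"}

    def test_age_independent_weights_give_similar_class_means(self, rng):
        # null simulation: BPI drawn independently of age
        n = 600
        df = pd.DataFrame({
            "sire_id": [f"s{i}" for i in range(n)],
            "bpi": rng.gamma(2.0, 0.5, size=n),
            "sire_age": rng.integers(1, 6, size=n),
        })
        out = age_summary(df)
        overall = df["bpi"].mean()
        for _, row in out.iterrows():
            se = row["sd"] / np.sqrt(row["n"])
            assert abs(row["mean"] - overall) < 3.5 * se
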