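import numpy as np
import pandas as pd
import pytest

from herdvigor.genotypes import MISSING
from herdvigor.simulate import (HerdSimulator, SimConfigError, SimParams,
                                _mendelian_offspring, apply_retention_rules,
                                draw_composite_composition,
                                draw_purebred_composition,
                                simulate_breed_compositions,
                                simulate_genotypes, simulate_herd)
from herdvigor.vigor import INDETERMINATE, RECOGNIZED_BREEDS, vigor_score


class TestCompositions:
    def test_purebred_draw_vigor_below_bound(self, rng):
        # with a main fraction >= 0.8 the score is at most 1 - 0.8^2 = 0.36
        for _ in range(50):
            comp = draw_purebred_composition(rng, RECOGNIZED_BREEDS)
            assert comp.sum() == pytest.approx(1.0)
            assert comp.max() >= 0.8
            assert vigor_score(comp) < 0.36

    def test_composite_draw_constraints(self, rng):
        for _ in range(50):
            comp = draw_composite_composition(rng, RECOGNIZED_BREEDS)
            named = comp[:-1]
            assert comp.sum() == pytest.approx(1.0)
            assert (named > 0).sum() >= 5
            assert named.max() <= 0.35

    def test_six_equal_breeds_closed_form(self):
        comp = np.zeros(len(RECOGNIZED_BREEDS) + 1)
        comp[:6] = 1.0 / 6.0
        assert vigor_score(comp) == pytest.approx(1 - 6 * (1 / 6) ** 2)

    def test_founder_pools_labelled(self):
        df = simulate_breed_compositions(SimParams(seed=3))
        assert set(df["pool"]) == {"purebred_sire", "composite_sire", "dam"}
        breed_cols = list(RECOGNIZED_BREEDS) + [INDETERMINATE]
        np.testing.assert_allclose(df[breed_cols].sum(axis=1), 1.0)

    def test_child_composition_is_parental_mean(self, sim):
        comps = sim.compositions.set_index("animal_id")
        calves = sim.herd.calves.dropna(subset=["dam_id"])
        sample = calves.head(20)
        for _, calf in sample.iterrows():
            child = comps.loc[calf["animal_id"]].to_numpy(dtype=float)
            dam = comps.loc[calf["dam_id"]].to_numpy(dtype=float)
            sire = comps.loc[calf["true_sire_id"]].to_numpy(dtype=float)
            np.testing.assert_allclose(child, 0.5 * (dam + sire), atol=1e-12)

    def test_too_few_breeds_rejected(self):
        with pytest.raises(SimConfigError, match="breeds"):
            SimParams(breeds=("Angus",))


class TestGenotypes:
    def test_mendelian_certainty(self, rng):
        two = np.full(10, 2)
        zero = np.zeros(10, dtype=int)
        np.testing.assert_array_equal(_mendelian_offspring(two, two, rng),
                                      np.full(10, 2))
        np.testing.assert_array_equal(_mendelian_offspring(zero, two, rng),
                                      np.ones(10))

    def test_founder_frequency_matches_configured(self, rng):
        # 500 founders of a single pure breed: observed allele frequency
        # should sit within 3 binomial SE of the configured frequency
        n, p = 500, 0.3
        params = SimParams(breeds=("A", "B"), n_snps=4, n_extension_snps=0,
                           seed=1)
        freqs = np.full((2, 4), p)
        comp = pd.DataFrame({"animal_id": [f"F{i}" for i in range(n)]})
        comp["A"] = 1.0
        comp["B"] = 0.0
        comp[INDETERMINATE] = 0.0
        panel = simulate_genotypes(comp, params, rng=rng,
                                   breed_allele_freqs=freqs)
        se = np.sqrt(p * (1 - p) / (2 * n))
        obs = panel.allele_frequencies()
        assert (np.abs(obs - p) < 3 * se).all()

    def test_error_rate_zero_keeps_mendelian_consistency(self, sim):
        panel = sim.panel
        for _, calf in sim.herd.calves.head(30).iterrows():
            c = panel.get(calf["animal_id"])
            s = panel.get(calf["true_sire_id"])
            opposing = ((c == 0) & (s == 2)) | ((c == 2) & (s == 0))
            assert opposing.sum() == 0


class TestBreedingSeason:
    def test_equal_weights_give_equal_shares(self):
        # 4 equal-weight sires: each observed calf share within 3 SE of 25%
        weights = {f"S{i:03d}": 1.0 for i in range(20)}
        params = SimParams(n_years=1, groups=((4, 1200),),
                           prolificacy_weights=weights,
                           conception_probs=(0.9, 0.8, 0.7, 0.6),
                           retention_fraction=0.0, seed=5)
        res = simulate_herd(params)
        calves = res.herd.calves
        n = len(calves)
        shares = calves.groupby("true_sire_id").size() / n
        se = np.sqrt(0.25 * 0.75 / n)
        assert len(shares) == 4
        assert (np.abs(shares - 0.25) < 3 * se).all()

    def test_zero_conception_probability_empty_season(self):
        params = SimParams(n_years=1, groups=((2, 50),),
                           conception_probs=(0.0, 0.0, 0.0, 0.0),
                           vs_effect_slopes={"conception_rate": 0.0},
                           seed=2)
        res = simulate_herd(params)
        assert len(res.herd.calves) == 0

    def test_every_calf_sire_is_in_its_group_roster(self, sim):
        herd = sim.herd
        for _, calf in herd.calves.iterrows():
            roster = herd.candidate_sires(int(calf["group"]), int(calf["year"]))
            assert calf["true_sire_id"] in roster

    def test_group_with_no_sires_rejected(self):
        with pytest.raises(SimConfigError, match="sire"):
            SimParams(groups=((0, 50),))

    def test_same_seed_reproduces_identical_herd(self):
        params = SimParams(n_years=2, groups=((3, 40), (2, 30)), seed=99)
        a = simulate_herd(params)
        b = simulate_herd(params)
        pd.testing.assert_frame_equal(a.herd.animals, b.herd.animals)
        np.testing.assert_array_equal(a.panel.calls, b.panel.calls)
        pd.testing.assert_frame_equal(a.compositions, b.compositions)


class TestRetention:
    def _crop(self):
        return pd.DataFrame({
            "animal_id": [f"H{i}" for i in range(10)],
            "dam_id": ["D0"] * 10,
            "weaning_weight": np.linspace(180.0, 260.0, 10),
        })

    def test_all_rules_off_full_fraction_keeps_everyone(self):
        params = SimParams(cull_rules=(), retention_fraction=1.0)
        retained, reasons = apply_retention_rules(self._crop(), params)
        assert len(retained) == 10
        assert reasons == []

    def test_retention_count_rounds_fraction_of_eligible(self):
        params = SimParams(cull_rules=(), retention_fraction=0.45)
        retained, _ = apply_retention_rules(self._crop(), params)
        assert len(retained) == round(0.45 * 10)

    def test_heaviest_heifers_kept(self):
        params = SimParams(cull_rules=(), retention_fraction=0.3)
        retained, _ = apply_retention_rules(self._crop(), params)
        assert retained == ["H7", "H8", "H9"]

    def test_third_cycle_heifer_culled_with_reason(self):
        params = SimParams(cull_rules=("third_cycle",), retention_fraction=1.0)
        cycle_of = {"H0": 3}
        retained, reasons = apply_retention_rules(self._crop(), params, cycle_of)
        assert "H0" not in retained
        assert {"animal_id": "H0", "reason": "third_cycle"} in reasons

    def test_overweight_dam_rule(self):
        params = SimParams(cull_rules=("dam_overweight",), retention_fraction=1.0)
        retained, reasons = apply_retention_rules(
            self._crop(), params, dam_weight_of={"D0": 800.0})
        assert retained == []
        assert all(r["reason"] == "dam_overweight" for r in reasons)

    def test_unweaned_heifers_never_retained(self):
        crop = self._crop()
        crop.loc[0, "weaning_weight"] = np.nan
        params = SimParams(cull_rules=(), retention_fraction=1.0)
        retained, reasons = apply_retention_rules(crop, params)
        assert "H0" not in retained
        assert {"animal_id": "H0", "reason": "not_weaned"} in reasons
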