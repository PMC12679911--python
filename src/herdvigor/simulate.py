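"""Synthetic multi-sire herd generator with known ground truth.

Emulates the structure of a western-Canadian commercial cow-calf herd run
with four multi-sire breeding groups per year over six breeding seasons:

* groups 1-2 hold mature cows (>= 3 years at calving) with 5-8 bulls each,
  group 3 holds cows calving at 3, group 4 holds replacement heifers
  calving at 2, with 2-4 bulls each — bull:cow ratios between 1:19 and 1:27;
* every dam that conceives does so in one of ``n_cycles`` 21-day cycles,
  with per-cycle baseline conception probabilities shifted by her genomic
  vigor score, producing a 69-85 day calving season;
* the sire of each conception is a weighted multinomial draw over the
  group's bulls (static per-sire prolificacy weights stand in for libido /
  dominance mechanisms);
* breed composition is inherited as the parental mean; SNP genotypes are
  transmitted Mendelianly from founders drawn at composition-weighted
  breed allele frequencies;
* heifer calves pass togglable culling rules, then the top
  ``retention_fraction`` by weaning weight are retained and enter the
  breeding herd to produce grand calves.

Every stochastic choice flows from a single seeded generator, so the whole
herd is a pure function of its parameters.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._util import log
from .genotypes import MISSING, GenotypePanel
from .herdbook import HerdBook
from .vigor import INDETERMINATE, RECOGNIZED_BREEDS, vigor_score

#: Per-10%-vigor-score trait effects injected by default: a 0.7-day drop in
#: age at first calving, +1.74 kg weaning weight, +2 percentage points
#: conception, +60.3 kg lifetime productivity.
DEFAULT_VS_SLOPES: dict[str, float] = {
    "afc_days": -0.7,
    "avg_ww_kg": 1.74,
    "conception_rate": 0.02,
    "lifetime_kg": 60.3,
}

#: (n_sires, n_dams) per breeding group, within the study's 1:19-1:27
#: bull:cow ratios: two mature-cow groups, one 3-yr-old group, one heifer group.
DEFAULT_GROUPS: tuple[tuple[int, int], ...] = ((6, 150), (6, 150), (3, 70), (3, 80))


class SimConfigError(ValueError):
    pass


@dataclass
class SimParams:
    """Knobs of the synthetic herd. Defaults mirror the emulated study herd."""

    n_years: int = 6
    start_year: int = 2014
    groups: tuple[tuple[int, int], ...] = DEFAULT_GROUPS
    prolificacy_weights: dict[str, float] | None = None
    prolificacy_shape: float = 1.5  # gamma shape of drawn per-sire weights
    conception_probs: tuple[float, ...] = (0.65, 0.55, 0.50, 0.45)
    n_cycles: int = 4
    cycle_length_days: int = 21
    vs_effect_slopes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_VS_SLOPES)
    )
    breeds: tuple[str, ...] = tuple(RECOGNIZED_BREEDS)
    breed_allele_freqs: np.ndarray | None = None  # breeds x loci
    n_snps: int = 100
    n_extension_snps: int = 20
    genotype_error_rate: float = 0.0
    retention_fraction: float = 0.5
    cull_rules: tuple[str, ...] = ("third_cycle", "dam_overweight")
    dam_weight_limit_kg: float = 771.0
    ww_base_kg: float = 200.0
    ww_sigma_kg: float = 15.0
    afc_sigma_days: float = 10.0
    wean_rate: float = 0.95  # calves with a recorded weaning weight
    vs_reference: float = 0.55  # VS at which baseline trait values apply
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.breeds or len(self.breeds) < 2:
            raise SimConfigError("at least 2 breeds must be configured")
        if any(n_s <= 0 or n_d <= 0 for n_s, n_d in self.groups):
            raise SimConfigError("every group needs >= 1 sire and >= 1 dam")
        if self.prolificacy_weights is not None and any(
            w <= 0 for w in self.prolificacy_weights.values()
        ):
            raise SimConfigError("prolificacy weights must be positive")
        if any(not 0 <= p <= 1 for p in self.conception_probs):
            raise SimConfigError("conception probabilities must lie in [0, 1]")
        if len(self.conception_probs) < self.n_cycles:
            raise SimConfigError(
                f"need {self.n_cycles} per-cycle conception probabilities"
            )
        if self.breed_allele_freqs is not None:
            f = np.asarray(self.breed_allele_freqs, dtype=float)
            if f.min() < 0 or f.max() > 1:
                raise SimConfigError("allele frequencies must lie in [0, 1]")
        if not 0 <= self.retention_fraction <= 1:
            raise SimConfigError("retention_fraction must lie in [0, 1]")
        if not 0 <= self.genotype_error_rate < 1:
            raise SimConfigError("genotype_error_rate must lie in [0, 1)")

    @property
    def n_loci(self) -> int:
        return self.n_snps + self.n_extension_snps


@dataclass
class GroundTruth:
    """What the simulator knows and the pipeline must recover."""

    sire_weights: dict[str, float]
    expected_share: dict[tuple[int, int], dict[str, float]]
    conception_cycle: dict[str, int]
    vs_effect_slopes: dict[str, float]
    cull_reasons: pd.DataFrame  # animal_id, reason

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"kind": "sire_weight", "key": s, "value": w}
            for s, w in sorted(self.sire_weights.items())
        ]
        rows += [
            {"kind": "conception_cycle", "key": a, "value": c}
            for a, c in sorted(self.conception_cycle.items())
        ]
        rows += [
            {"kind": "vs_slope", "key": t, "value": v}
            for t, v in self.vs_effect_slopes.items()
        ]
        return pd.DataFrame(rows, columns=["kind", "key", "value"])


@dataclass
class SimResult:
    herd: HerdBook
    panel: GenotypePanel
    compositions: pd.DataFrame  # animal_id + breed columns + indeterminate
    truth: GroundTruth


# -- composition draws -------------------------------------------------------

def draw_purebred_composition(rng: np.random.Generator, breeds,
                              main: str = "Angus") -> np.ndarray:
    """Purebred-like vector: one breed >= 0.8, remainder thinly spread."""
    breeds = list(breeds)
    comp = np.zeros(len(breeds) + 1)
    main_frac = rng.uniform(0.80, 0.92)
    comp[breeds.index(main)] = main_frac
    others = rng.choice([i for i in range(len(breeds)) if breeds[i] != main],
                        size=2, replace=False)
    rest = rng.dirichlet(np.ones(3)) * (1.0 - main_frac)
    comp[others[0]] += rest[0]
    comp[others[1]] += rest[1]
    comp[-1] = rest[2]  # indeterminate
    return comp


def draw_composite_composition(rng: np.random.Generator, breeds,
                               n_components: int = 6,
                               max_fraction: float = 0.35) -> np.ndarray:
    """Composite-like vector: >= 5 breeds, no single breed above 0.35."""
    breeds = list(breeds)
    if n_components < 5:
        raise SimConfigError("composite draws need >= 5 contributing breeds")
    idx = rng.choice(len(breeds), size=n_components, replace=False)
    for _ in range(1000):
        named = rng.dirichlet(np.full(n_components, 3.0))
        indet = rng.uniform(0.0, 0.05)
        named = named * (1.0 - indet)
        if named.max() <= max_fraction:
            comp = np.zeros(len(breeds) + 1)
            comp[idx] = named
            comp[-1] = indet
            return comp
    raise RuntimeError("composite composition rejection sampling failed")


def draw_dam_composition(rng: np.random.Generator, breeds) -> np.ndarray:
    """Dam pool sits between the purebred-like and composite-like pools."""
    lam = rng.uniform(0.0, 1.0)
    pure = draw_purebred_composition(rng, breeds)
    comp = draw_composite_composition(rng, breeds)
    return lam * pure + (1.0 - lam) * comp


def simulate_breed_compositions(params: SimParams,
                                rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Founder composition pools (purebred-like sires, composite-like sires,
    dams), one row per founder, columns = breeds + indeterminate + pool."""
    rng = rng or np.random.default_rng(params.seed)
    n_sires = sum(g[0] for g in params.groups)
    n_dams = sum(g[1] for g in params.groups)
    n_pure = max(1, round(0.2 * n_sires))
    rows, pools, ids = [], [], []
    for i in range(n_pure):
        rows.append(draw_purebred_composition(rng, params.breeds))
        pools.append("purebred_sire")
        ids.append(f"FS{i:03d}")
    for i in range(n_pure, n_sires):
        rows.append(draw_composite_composition(rng, params.breeds))
        pools.append("composite_sire")
        ids.append(f"FS{i:03d}")
    for i in range(n_dams):
        rows.append(draw_dam_composition(rng, params.breeds))
        pools.append("dam")
        ids.append(f"FD{i:03d}")
    df = pd.DataFrame(rows, columns=list(params.breeds) + [INDETERMINATE])
    df.insert(0, "animal_id", ids)
    df["pool"] = pools
    return df


# -- genotypes ----------------------------------------------------------------

def default_breed_allele_freqs(params: SimParams,
                               rng: np.random.Generator) -> np.ndarray:
    """Moderately informative per-breed reference-allele frequencies.

    Parentage panels are chosen for intermediate allele frequencies, so the
    base frequency is uniform on (0.25, 0.75) with breed-specific drift.
    """
    base = rng.uniform(0.25, 0.75, size=params.n_loci)
    drift = rng.normal(0.0, 0.15, size=(len(params.breeds), params.n_loci))
    return np.clip(base + drift, 0.05, 0.95)


def _founder_genotype(comp: np.ndarray, freqs: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    # effective allele frequency = composition-weighted breed frequency;
    # the indeterminate fraction contributes at frequency 0.5
    p = comp[:-1] @ freqs + comp[-1] * 0.5
    return rng.binomial(2, p).astype(np.int8)


def _mendelian_offspring(dam_g: np.ndarray, sire_g: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    a_dam = rng.binomial(1, dam_g / 2.0)
    a_sire = rng.binomial(1, sire_g / 2.0)
    return (a_dam + a_sire).astype(np.int8)


def _apply_genotype_errors(calls: np.ndarray, rate: float,
                           rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return calls
    flip = rng.random(calls.shape) < rate
    shift = rng.integers(1, 3, size=calls.shape)  # move to one of the 2 others
    return np.where(flip, (calls + shift) % 3, calls).astype(np.int8)


def simulate_genotypes(compositions: pd.DataFrame, params: SimParams,
                       pedigree: dict[str, tuple[str | None, str | None]] | None = None,
                       rng: np.random.Generator | None = None,
                       breed_allele_freqs: np.ndarray | None = None) -> GenotypePanel:
    """Draw a genotype panel for the animals of a composition table.

    Founders (no pedigree entry) are drawn per-locus at their composition-
    weighted allele frequency; animals with recorded parents receive one
    Mendelian allele from each. Genotyping errors perturb calls at
    ``genotype_error_rate``.
    """
    rng = rng or np.random.default_rng(params.seed)
    freqs = breed_allele_freqs
    if freqs is None:
        freqs = (params.breed_allele_freqs
                 if params.breed_allele_freqs is not None
                 else default_breed_allele_freqs(params, rng))
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape[0] != len(params.breeds):
        raise SimConfigError(
            "breed_allele_freqs must have one row per configured breed"
        )
    pedigree = pedigree or {}
    breed_cols = list(params.breeds) + [INDETERMINATE]
    comp_of = {
        str(r["animal_id"]): r[breed_cols].to_numpy(dtype=float)
        for _, r in compositions.iterrows()
    }
    geno: dict[str, np.ndarray] = {}

    def _resolve(aid: str) -> np.ndarray:
        if aid in geno:
            return geno[aid]
        dam, sire = pedigree.get(aid, (None, None))
        if dam is None or sire is None or dam not in comp_of or sire not in comp_of:
            g = _founder_genotype(comp_of[aid], freqs, rng)
        else:
            g = _mendelian_offspring(_resolve(dam), _resolve(sire), rng)
        geno[aid] = g
        return g

    animals = [str(a) for a in compositions["animal_id"]]
    calls = np.vstack([_resolve(a) for a in animals])
    calls = _apply_genotype_errors(calls, params.genotype_error_rate, rng)
    loci = [f"SNP{j:04d}" for j in range(freqs.shape[1])]
    return GenotypePanel(animals, loci, calls)


# -- retention rules ---------------------------------------------------------

def apply_retention_rules(heifers: pd.DataFrame, params: SimParams,
                          cycle_of: dict[str, int] | None = None,
                          dam_weight_of: dict[str, float] | None = None,
                          ) -> tuple[list[str], list[dict]]:
    """Cull heifers by the configured named rules, then keep the heaviest
    ``retention_fraction`` of the survivors by weaning weight.

    Returns (retained ids, cull log rows with reason codes).
    """
    cycle_of = cycle_of or {}
    dam_weight_of = dam_weight_of or {}
    reasons: list[dict] = []
    eligible = []
    for _, row in heifers.iterrows():
        aid = str(row["animal_id"])
        reason = None
        if pd.isna(row.get("weaning_weight")):
            reason = "not_weaned"
        elif "third_cycle" in params.cull_rules and cycle_of.get(aid, 1) >= 3:
            reason = "third_cycle"
        elif ("dam_overweight" in params.cull_rules
              and dam_weight_of.get(str(row.get("dam_id")), 0.0)
              > params.dam_weight_limit_kg):
            reason = "dam_overweight"
        if reason is not None:
            reasons.append({"animal_id": aid, "reason": reason})
            log.debug("heifer %s culled: %s", aid, reason)
        else:
            eligible.append((aid, float(row["weaning_weight"])))
    n_keep = round(params.retention_fraction * len(eligible))
    # heaviest first; ties broken by id for determinism
    eligible.sort(key=lambda t: (-t[1], t[0]))
    retained = sorted(aid for aid, _ in eligible[:n_keep])
    for aid, _ in eligible[n_keep:]:
        reasons.append({"animal_id": aid, "reason": "below_retention_cut"})
    return retained, reasons


def simulate_retention(herd: HerdBook, params: SimParams,
                       cycle_of: dict[str, int] | None = None,
                       dam_weight_of: dict[str, float] | None = None) -> HerdBook:
    """Set retention flags on every heifer calf crop of a herd book."""
    animals = herd.animals.copy()
    all_reasons: list[dict] = []
    for year in sorted(animals.loc[animals["year"].notna(), "year"].unique()):
        crop = animals[(animals["year"] == year) & (animals["sex"] == "F")
                       & animals["dam_id"].notna()]
        retained, reasons = apply_retention_rules(
            crop, params, cycle_of, dam_weight_of)
        animals.loc[animals["animal_id"].isin(retained), "retained"] = True
        all_reasons.extend(reasons)
    return HerdBook(animals, herd.sire_groups)


# -- trait-only generator (regression oracle conditions) ---------------------

def simulate_trait_records(n: int, rng: np.random.Generator,
                           slopes: dict[str, float] | None = None,
                           vs_mean: float = 0.65, vs_sd: float = 0.15,
                           afc_base: float = 730.0, afc_sigma: float = 10.0,
                           ww_base: float = 200.0, ww_sigma: float = 15.0,
                           lifetime_base: float = 600.0,
                           lifetime_sigma: float = 50.0,
                           conception_base: float = 0.85) -> pd.DataFrame:
    """Heifer-level trait records with exactly injected per-10%-VS effects.

    Used to check that the regression stage recovers known slopes: each
    trait is linear in (VS - vs_mean)/0.10 plus Gaussian noise (conception
    is Bernoulli with a linear probability).
    """
    slopes = dict(DEFAULT_VS_SLOPES if slopes is None else slopes)
    vs = np.clip(rng.normal(vs_mean, vs_sd, size=n), 0.05, 0.95)
    x = (vs - vs_mean) / 0.10
    p = np.clip(conception_base + slopes["conception_rate"] * x, 0.01, 0.99)
    return pd.DataFrame({
        "vigor_score": vs,
        "afc_days": afc_base + slopes["afc_days"] * x
        + rng.normal(0, afc_sigma, n),
        "avg_ww_kg": ww_base + slopes["avg_ww_kg"] * x
        + rng.normal(0, ww_sigma, n),
        "lifetime_kg": lifetime_base + slopes["lifetime_kg"] * x
        + rng.normal(0, lifetime_sigma, n),
        "conception_rate": rng.binomial(1, p).astype(float),
    })


# -- full herd simulation -----------------------------------------------------

class HerdSimulator:
    """Stateful multi-year simulation driven by a single seeded generator."""

    def __init__(self, params: SimParams):
        self.params = params
        self.rng = np.random.default_rng(params.seed)
        self.breeds = list(params.breeds)
        self.freqs = (
            np.asarray(params.breed_allele_freqs, dtype=float)
            if params.breed_allele_freqs is not None
            else default_breed_allele_freqs(params, self.rng)
        )
        self.records: list[dict] = []
        self.comp_of: dict[str, np.ndarray] = {}
        self.pedigree: dict[str, tuple[str | None, str | None]] = {}
        self.sire_weights: dict[str, float] = {}
        self.dam_weights_kg: dict[str, float] = {}
        self.conception_cycle: dict[str, int] = {}
        self.expected_share: dict[tuple[int, int], dict[str, float]] = {}
        self.roster_rows: list[dict] = []
        self.cull_log: list[dict] = []
        self._calf_counter = 0
        self._sire_counter = 0
        self._dam_counter = 0
        self._active_sires: list[str] = []
        self._active_dams: list[str] = []
        self._disposed: dict[str, int] = {}

    # -- bookkeeping helpers ------------------------------------------------
    def _add_animal(self, aid: str, sex: str, birth_date: _dt.date,
                    comp: np.ndarray, dam: str | None = None,
                    sire: str | None = None, group=None, year=None,
                    birth_weight=None, weaning_weight=None) -> None:
        self.records.append({
            "animal_id": aid, "sex": sex, "birth_date": birth_date,
            "dam_id": dam, "true_sire_id": sire, "assigned_sire_id": None,
            "group": group, "year": year, "birth_weight": birth_weight,
            "weaning_weight": weaning_weight, "retained": False,
            "disposal_year": None,
        })
        self.comp_of[aid] = comp
        self.pedigree[aid] = (dam, sire)

    def _new_sire(self, birth_year: int, purebred: bool) -> str:
        aid = f"S{self._sire_counter:03d}"
        self._sire_counter += 1
        comp = (draw_purebred_composition(self.rng, self.breeds) if purebred
                else draw_composite_composition(self.rng, self.breeds))
        self._add_animal(aid, "M", _dt.date(birth_year, 4, 15), comp)
        if self.params.prolificacy_weights and aid in self.params.prolificacy_weights:
            w = self.params.prolificacy_weights[aid]
        else:
            shape = self.params.prolificacy_shape
            w = float(self.rng.gamma(shape, 1.0 / shape))
            w = max(w, 0.02)
        self.sire_weights[aid] = w
        return aid

    def _new_founder_dam(self, birth_year: int) -> str:
        aid = f"D{self._dam_counter:04d}"
        self._dam_counter += 1
        comp = draw_dam_composition(self.rng, self.breeds)
        self._add_animal(aid, "F", _dt.date(birth_year, 4, 10), comp)
        self.dam_weights_kg[aid] = float(self.rng.normal(640.0, 55.0))
        return aid

    def _vs(self, aid: str) -> float:
        return vigor_score(self.comp_of[aid])

    # -- season mechanics ----------------------------------------------------
    def _setup_founders(self) -> None:
        p = self.params
        y0 = p.start_year
        n_sires = sum(g[0] for g in p.groups)
        n_pure = max(1, round(0.2 * n_sires))
        for i in range(n_sires + 4):  # roster plus injury spares
            age = int(self.rng.integers(1, 6))
            self._active_sires.append(self._new_sire(y0 - age, i < n_pure))
        # dam age structure by group role: heifers calve at 2, group 3 at 3
        for gi, (_, n_dams) in enumerate(p.groups):
            for _ in range(n_dams):
                if gi == 3:
                    age = 1
                elif gi == 2:
                    age = 2
                else:
                    age = int(self.rng.integers(3, 9))
                self._active_dams.append(self._new_founder_dam(y0 - age))

    def _assign_groups(self, year: int) -> tuple[dict[int, list[str]], dict[int, list[str]]]:
        """Allocate active dams by age class and sires by roster size."""
        p = self.params
        born = {a: r["birth_date"].year for a, r in
                ((rec["animal_id"], rec) for rec in self.records)
                }
        n_groups = len(p.groups)
        heifer_g = 4 if n_groups >= 4 else n_groups
        young_g = 3 if n_groups >= 3 else n_groups
        mature_gs = [1, 2] if n_groups >= 2 else [1]
        dam_groups: dict[int, list[str]] = {g: [] for g in
                                            range(1, n_groups + 1)}
        for dam in self._active_dams:
            age = year - born[dam]
            if age <= 1:
                dam_groups[heifer_g].append(dam)
            elif age == 2:
                dam_groups[young_g].append(dam)
            else:
                # split mature cows across the mature groups deterministically
                target = min(mature_gs, key=lambda g: len(dam_groups[g]))
                dam_groups[target].append(dam)
        sires = list(self._active_sires)
        self.rng.shuffle(sires)
        sire_groups: dict[int, list[str]] = {}
        k = 0
        for gi, (n_s, _) in enumerate(p.groups, start=1):
            take = min(n_s, len(sires) - k) if gi < len(p.groups) else len(sires) - k
            take = min(n_s, max(take, 1))
            sire_groups[gi] = sires[k:k + take]
            k += take
        return sire_groups, dam_groups

    def simulate_breeding_season(self, year: int) -> None:
        """One breeding season: conceptions, sire draws, calvings, weaning."""
        p = self.params
        sire_groups, dam_groups = self._assign_groups(year)
        season_anchor = _dt.date(year + 1, 4, 1)
        for gi in sorted(sire_groups):
            sires = sire_groups[gi]
            dams = dam_groups.get(gi, [])
            if not sires:
                raise SimConfigError(f"group {gi} in {year} has no sires")
            for s in sires:
                self.roster_rows.append({"sire_id": s, "group": gi, "year": year})
            w = np.array([self.sire_weights[s] for s in sires])
            share = w / w.sum()
            self.expected_share[(gi, year)] = dict(zip(sires, share))
            slope_conc = p.vs_effect_slopes.get("conception_rate", 0.0)
            slope_ww = p.vs_effect_slopes.get("avg_ww_kg", 0.0)
            for dam in dams:
                dam_vs = self._vs(dam)
                x = (dam_vs - p.vs_reference) / 0.10
                cycle = None
                for c in range(1, p.n_cycles + 1):
                    prob = float(np.clip(
                        p.conception_probs[c - 1] + slope_conc * x, 0.0, 1.0))
                    if self.rng.random() < prob:
                        cycle = c
                        break
                if cycle is None:
                    continue
                sire = sires[int(self.rng.choice(len(sires), p=share))]
                day = (cycle - 1) * p.cycle_length_days + int(
                    self.rng.integers(0, p.cycle_length_days))
                birth = season_anchor + _dt.timedelta(days=day)
                aid = f"C{self._calf_counter:05d}"
                self._calf_counter += 1
                sex = "F" if self.rng.random() < 0.5 else "M"
                weaned = self.rng.random() < p.wean_rate
                ww = (p.ww_base_kg + slope_ww * x
                      + self.rng.normal(0.0, p.ww_sigma_kg)) if weaned else None
                comp = 0.5 * (self.comp_of[dam] + self.comp_of[sire])
                self._add_animal(
                    aid, sex, birth, comp, dam=dam, sire=sire, group=gi,
                    year=year, birth_weight=float(self.rng.normal(38.0, 4.0)),
                    weaning_weight=ww,
                )
                self.conception_cycle[aid] = cycle

    def _retain_heifers(self, year: int) -> None:
        p = self.params
        crop = pd.DataFrame([r for r in self.records
                             if r["year"] == year and r["sex"] == "F"])
        if crop.empty:
            return
        retained, reasons = apply_retention_rules(
            crop, p, self.conception_cycle, self.dam_weights_kg)
        self.cull_log.extend(reasons)
        retained_set = set(retained)
        for rec in self.records:
            if rec["animal_id"] in retained_set:
                rec["retained"] = True
                self.dam_weights_kg[rec["animal_id"]] = float(
                    self.rng.normal(620.0, 50.0))

    def _turnover(self, year: int, calved: set[str]) -> None:
        """Age-, openness- and chance-driven exits; recruit replacements."""
        p = self.params
        born = {rec["animal_id"]: rec["birth_date"].year for rec in self.records}
        survivors = []
        for dam in self._active_dams:
            age = year - born[dam]
            p_exit = 0.08 + (0.30 if dam not in calved else 0.0) \
                + (0.20 if age >= 9 else 0.0)
            if self.rng.random() < p_exit:
                self._disposed[dam] = year
            else:
                survivors.append(dam)
        self._active_dams = survivors
        # a retained heifer from the crop of breeding year y is born in
        # spring y+1 and enters the breeding herd in July y+2 at ~15 months
        entrants = [rec["animal_id"] for rec in self.records
                    if rec["retained"] and rec["year"] == year - 2]
        self._active_dams.extend(entrants)
        keep = []
        for s in self._active_sires:
            age = year - born[s]
            if age >= 6 or self.rng.random() < 0.12:
                self._disposed[s] = year
            else:
                keep.append(s)
        self._active_sires = keep
        needed = sum(g[0] for g in p.groups) + 2
        while len(self._active_sires) < needed:
            self._active_sires.append(self._new_sire(year, self.rng.random() < 0.2))

    def run(self) -> SimResult:
        p = self.params
        self._setup_founders()
        for year in range(p.start_year, p.start_year + p.n_years):
            self.simulate_breeding_season(year)
            self._retain_heifers(year)
            calved = {rec["dam_id"] for rec in self.records
                      if rec["year"] == year and rec["dam_id"]}
            self._turnover(year + 1, calved)
        animals = pd.DataFrame(self.records)
        animals["disposal_year"] = animals["animal_id"].map(
            lambda a: self._disposed.get(a))
        roster = pd.DataFrame(self.roster_rows)
        herd = HerdBook(animals, roster)
        compositions = pd.DataFrame(
            [self.comp_of[a] for a in animals["animal_id"]],
            columns=self.breeds + [INDETERMINATE],
        )
        compositions.insert(0, "animal_id", animals["animal_id"].to_numpy())
        panel = simulate_genotypes(
            compositions, p, pedigree=self.pedigree, rng=self.rng,
            breed_allele_freqs=self.freqs,
        )
        truth = GroundTruth(
            sire_weights=dict(self.sire_weights),
            expected_share=dict(self.expected_share),
            conception_cycle=dict(self.conception_cycle),
            vs_effect_slopes=dict(p.vs_effect_slopes),
            cull_reasons=pd.DataFrame(self.cull_log,
                                      columns=["animal_id", "reason"]),
        )
        log.info("simulated herd: %d animals, %d calves over %d years",
                 len(animals), len(self.conception_cycle), p.n_years)
        return SimResult(herd=herd, panel=panel, compositions=compositions,
                         truth=truth)


def simulate_herd(params: SimParams | None = None, seed: int | None = None) -> SimResult:
    """Convenience wrapper: run a full multi-year herd simulation."""
    params = params or SimParams()
    if seed is not None:
        params = replace(params, seed=seed)
    return HerdSimulator(params).run()
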