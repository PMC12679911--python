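"""Model/Results facade tying the pipeline stages together.

``HerdVigorModel`` is built from the input tables (herd book + sire
roster, optional SNP panel, optional breed compositions) and a
``RunConfig``; ``fit()`` executes parentage -> prolificacy -> calving
cycles -> vigor -> cohort accounting -> trait regressions and returns a
``HerdVigorResults`` holding every stage's table, a ``summary()`` text
report, per-stage CSV export and basic plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import log, round_half_up
from .config import RunConfig
from .cohort import (build_cohort_table, first_cycle_linkage,
                     per_sire_first_cycle_shares)
from .cycles import assign_cycles, cycle_distribution
from .genotypes import GenotypePanel, read_genotypes
from .herdbook import HerdBook, read_herdbook, write_herdbook
from .parentage import apply_assignments, verification_summary, verify_parentage
from .prolificacy import (age_summary, bpi_range_table, bpi_table,
                          repeatability, strata_frame, stratify_sires)
from .regression import (compare_to_benchmarks, estimate_all_slopes,
                         heifer_trait_records, vs_cutoff_sensitivity)
from .vigor import bin_by_vigor, composition_table_scores


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class HerdVigorResults:
    """Fitted pipeline output; one attribute per stage table."""

    config: RunConfig
    parentage: pd.DataFrame
    verification: tuple[int, int, int]
    cycles: pd.DataFrame
    cycle_dist: pd.DataFrame
    bpi_records: pd.DataFrame
    bpi_ranges: pd.DataFrame
    strata: pd.DataFrame
    repeatability: pd.DataFrame
    age_summary: pd.DataFrame
    vigor: pd.DataFrame
    vigor_bins: pd.DataFrame
    cohort: pd.DataFrame
    linkage: pd.DataFrame
    slopes: pd.DataFrame
    sensitivity: pd.DataFrame
    heifer_traits: pd.DataFrame = field(default_factory=pd.DataFrame)

    # -- reporting -----------------------------------------------------------
    def summary(self) -> str:
        tested, matched, unmatched = self.verification
        lines = ["Herd vigor analysis", "=" * 19, ""]
        lines.append(
            f"Parentage: {tested} calves tested, {matched} sires verified, "
            f"{unmatched} no-sire-match"
            + (f" ({100 * matched / tested:.1f}% match rate)" if tested else "")
        )
        served = self.bpi_records[self.bpi_records["n"] > 0]
        if not served.empty:
            lines.append(
                f"BPI: {len(served)} sire-year indexes for "
                f"{served['sire_id'].nunique()} sires; median "
                f"{served['bpi'].median():.2f}, mean {served['bpi'].mean():.2f}, "
                f"range {served['bpi'].min():.2f}-{served['bpi'].max():.2f}"
            )
        if not self.strata.empty:
            per = self.strata.groupby("stratum")["avg_bpi"].first()
            lines.append("Sire strata (avg BPI): " + ", ".join(
                f"{k} {v:.2f}" for k, v in per.items()))
        if not self.cycle_dist.empty:
            first = self.cycle_dist[self.cycle_dist["cycle"] == 1]
            ok = first["meets_benchmark"].sum()
            lines.append(
                f"Calving cycles: mean first-cycle share "
                f"{first['percent'].mean():.0f}%; "
                f"{ok}/{len(first)} group-years meet the "
                f"{100 * self.config.first_cycle_benchmark:.0f}% benchmark"
            )
        if not self.vigor.empty:
            lines.append(
                f"Vigor scores: n={len(self.vigor)}, mean "
                f"{self.vigor['vigor_score'].mean():.2f}, range "
                f"{self.vigor['vigor_score'].min():.2f}-"
                f"{self.vigor['vigor_score'].max():.2f}"
            )
        if not self.slopes.empty:
            lines.append("")
            lines.append("Per-10%-vigor-score trait effects vs benchmarks:")
            lines.append(f"{'trait':<16}{'slope':>9}{'SE':>8}{'p':>8}"
                         f"{'benchmark':>11}{'agrees':>8}")
            for _, r in self.slopes.iterrows():
                lines.append(
                    f"{r['trait']:<16}{r['slope_per_10pct']:>9.2f}"
                    f"{r['std_error']:>8.2f}{r['p_value']:>8.3f}"
                    f"{r['benchmark']:>11.2f}"
                    f"{'yes' if r['direction_agrees'] else 'no':>8}"
                )
        if not self.cohort.empty:
            lines.append("")
            lines.append("Cohort accounting (per heifer crop and sire stratum):")
            for _, r in self.cohort.iterrows():
                if r["stratum"] == "Total":
                    lines.append(
                        f"  {r['birth_year']} Total: {r['n_daughters_retained']}"
                        f" retained, {r['pct_remaining']}% remaining"
                    )
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> None:
        """Write every stage table as CSV plus the text summary."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tables = {
            "parentage.csv": self.parentage,
            "cycles.csv": self.cycles,
            "cycle_distribution.csv": self.cycle_dist,
            "bpi.csv": self.bpi_records,
            "bpi_ranges.csv": self.bpi_ranges,
            "strata.csv": self.strata,
            "repeatability.csv": self.repeatability,
            "age_summary.csv": self.age_summary,
            "vigor.csv": self.vigor,
            "vigor_bins.csv": self.vigor_bins,
            "cohort.csv": self.cohort,
            "first_cycle_linkage.csv": self.linkage,
            "slopes.csv": self.slopes,
            "slope_sensitivity.csv": self.sensitivity,
            "heifer_traits.csv": self.heifer_traits,
        }
        for name, df in tables.items():
            df.to_csv(outdir / name, index=False)
        (outdir / "summary.txt").write_text(self.summary() + "\n")

    def plot_cycle_distribution(self, ax=None):
        """Bar chart of per-cycle birth percentages by group-year."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pivot = self.cycle_dist.pivot_table(
            index=["year", "group"], columns="cycle", values="percent",
            fill_value=0.0)
        pivot.plot(kind="bar", stacked=True, ax=ax)
        ax.axhline(100 * self.config.first_cycle_benchmark, ls="--", c="k")
        ax.set_ylabel("% of calf crop")
        return ax

    def plot_slopes(self, ax=None):
        """Estimated per-10%-VS effects with CIs against the benchmarks."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.slopes
        x = np.arange(len(df))
        ax.errorbar(x, df["slope_per_10pct"], yerr=1.96 * df["std_error"],
                    fmt="o", label="estimate")
        ax.scatter(x, df["benchmark"], marker="x", c="r", label="benchmark")
        ax.set_xticks(x, df["trait"], rotation=30)
        ax.axhline(0, c="grey", lw=0.5)
        ax.legend()
        return ax


class HerdVigorModel:
    """Herd analysis model over a herd book, SNP panel and GBC table.

    Parameters
    ----------
    herd : HerdBook
    panel : GenotypePanel, optional
        When present, sire assignment is DNA-based; otherwise existing
        ``assigned_sire_id`` entries are used as-is.
    compositions : DataFrame, optional
        animal_id + breed-fraction columns (+ indeterminate); enables the
        vigor and regression stages.
    config : RunConfig
    """

    def __init__(self, herd: HerdBook, panel: GenotypePanel | None = None,
                 compositions: pd.DataFrame | None = None,
                 config: RunConfig | None = None):
        self.herd = herd
        self.panel = panel
        self.compositions = compositions
        self.config = config or RunConfig()

    @classmethod
    def from_csv(cls, herdbook_path, sire_groups_path=None,
                 genotypes_path=None, genotype_dialect="matrix-tsv",
                 compositions_path=None, config: RunConfig | None = None
                 ) -> "HerdVigorModel":
        herd = read_herdbook(herdbook_path, sire_groups_path)
        panel = (read_genotypes(genotypes_path, genotype_dialect)
                 if genotypes_path else None)
        comps = (pd.read_csv(compositions_path, dtype={"animal_id": str})
                 if compositions_path else None)
        return cls(herd, panel, comps, config)

    @classmethod
    def from_simulation(cls, params=None, seed: int | None = None,
                        config: RunConfig | None = None) -> "HerdVigorModel":
        from .simulate import simulate_herd

        sim = simulate_herd(params, seed=seed)
        return cls(sim.herd, sim.panel, sim.compositions, config)

    # -- fitting --------------------------------------------------------------
    def fit(self, heifer_birth_years: list[int] | None = None
            ) -> HerdVigorResults:
        cfg = self.config
        rng = np.random.default_rng(cfg.rng_seed)
        herd = self.herd

        def stage(name, fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage
                raise PipelineError(name, exc) from exc

        if self.panel is not None:
            par = stage("parentage", verify_parentage, herd, self.panel, cfg)
            herd = stage("parentage", apply_assignments, herd, par)
        else:
            assigned = herd.animals[herd.animals["assigned_sire_id"].notna()]
            par = pd.DataFrame({
                "calf_id": assigned["animal_id"],
                "assigned_sire_id": assigned["assigned_sire_id"],
                "n_candidates": np.nan, "min_opposing_homozygotes": np.nan,
                "panel_size_used": np.nan, "status": "from_records",
            })
        verification = verification_summary(par)

        cyc = stage("cycles", assign_cycles, herd, cfg)
        cyc_dist = stage("cycles", cycle_distribution, cyc,
                         cfg.first_cycle_benchmark)

        records = stage("bpi", bpi_table, par, herd, cyc)
        ranges = stage("bpi", bpi_range_table, records)
        strata = stage("bpi", stratify_sires, records)
        rep = stage("bpi", repeatability, records, 999, rng)
        ages = stage("bpi", age_summary, records)

        if self.compositions is not None:
            vig = stage("vigor", composition_table_scores, self.compositions,
                        cfg.include_indeterminate)
            merged = vig.merge(self.compositions, on="animal_id")
            bins = stage("vigor", bin_by_vigor, merged.drop(columns=["vs_bin"]))
        else:
            vig = pd.DataFrame(columns=["animal_id", "vigor_score", "vs_bin"])
            bins = pd.DataFrame(columns=["vs_bin", "n"])

        crop_years = sorted(int(y) for y in
                            herd.calves["year"].dropna().unique())
        if heifer_birth_years is None:
            # default: the earliest crops whose daughters have at least two
            # later calf crops on record (the published table uses two)
            heifer_birth_years = [y for y in crop_years
                                  if y + 3 <= max(crop_years)][:2]
        cohort_df = stage(
            "cohort", build_cohort_table, herd, strata, heifer_birth_years,
            None, cfg.use_rounded_grandcalf_average,
        ) if heifer_birth_years and strata else pd.DataFrame()
        shares = stage("cohort", per_sire_first_cycle_shares, herd, cyc,
                       heifer_birth_years) if heifer_birth_years else pd.DataFrame()
        linkage = (stage("cohort", first_cycle_linkage, shares, strata)
                   if not shares.empty and strata else pd.DataFrame())

        if not vig.empty:
            traits = stage("regress", heifer_trait_records, herd, vig,
                           heifer_birth_years or None)
            estimates = stage("regress", estimate_all_slopes, traits)
            slopes = stage("regress", compare_to_benchmarks, estimates,
                           cfg.benchmark_slopes)
            sens_frames = []
            for trait in ("afc_days", "avg_ww_kg", "lifetime_kg"):
                sub = traits[["vigor_score", trait]].dropna()
                if len(sub) >= 3 and sub["vigor_score"].var() > 0:
                    sens_frames.append(vs_cutoff_sensitivity(
                        sub["vigor_score"], sub[trait], trait=trait,
                        cutoff=cfg.vs_cutoff))
            sens = (pd.concat(sens_frames, ignore_index=True)
                    if sens_frames else pd.DataFrame())
        else:
            traits = pd.DataFrame()
            slopes = pd.DataFrame()
            sens = pd.DataFrame()

        log.info("pipeline complete: %d calves, %d BPI records",
                 verification[0], len(records))
        return HerdVigorResults(
            config=cfg, parentage=par, verification=verification,
            cycles=cyc, cycle_dist=cyc_dist, bpi_records=records,
            bpi_ranges=ranges, strata=strata_frame(strata),
            repeatability=rep, age_summary=ages, vigor=vig, vigor_bins=bins,
            cohort=cohort_df, linkage=linkage, slopes=slopes,
            sensitivity=sens, heifer_traits=traits,
        )


def run_pipeline(config: RunConfig, herdbook_path, sire_groups_path=None,
                 genotypes_path=None, genotype_dialect="matrix-tsv",
                 compositions_path=None, outdir=None) -> HerdVigorResults:
    """File-level pipeline entry point: read inputs, fit, optionally save."""
    model = HerdVigorModel.from_csv(
        herdbook_path, sire_groups_path, genotypes_path, genotype_dialect,
        compositions_path, config)
    results = model.fit()
    if outdir is not None:
        results.save(outdir)
    return results
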