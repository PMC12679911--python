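"""Retained-daughter cohort accounting by sire prolificacy stratum.

Tracks the daughters each sire stratum contributed to the replacement
herd and their downstream production: per-calving-year calf counts, the
percentage of retained heifers still calving in the final tabulated year,
total calves weaned, average grand calves per sire and total weaned
weight per sire. Daughters are attributed to sires by DNA-verified
parentage (assigned_sire_id), never by herd-book sire fields.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._util import round_half_up
from .herdbook import HerdBook
from .prolificacy import SireStratum

# -- the printed-table arithmetic, exposed as small pure functions ----------

def pct_remaining(last_year_calvers: int, n_retained: int,
                  ndigits: int = 1) -> float:
    """Percent of retained daughters still calving in the final tabulated
    year: 100 * last_year_calvers / n_retained, at table precision."""
    if n_retained <= 0:
        raise ZeroDivisionError("no retained daughters")
    return round_half_up(100.0 * last_year_calvers / n_retained, ndigits)


def grandcalves_per_sire(total_calves_weaned: int, n_sires: int) -> float:
    """Average grand calves per sire, printed at one decimal."""
    if n_sires <= 0:
        raise ZeroDivisionError("no sires in stratum")
    return round_half_up(total_calves_weaned / n_sires, 1)


def total_kg_weaned_per_sire(avg_ww_per_calf: float,
                             avg_grandcalves_per_sire: float,
                             use_rounded_average: bool = True) -> float:
    """Average weaning weight x average grand calves per sire.

    With ``use_rounded_average`` the one-decimal-rounded calf average is
    used, matching how the published accounting multiplies its printed
    cells; the unrounded variant is available for real analyses.
    """
    avg = (round_half_up(avg_grandcalves_per_sire, 1)
           if use_rounded_average else avg_grandcalves_per_sire)
    return round_half_up(avg_ww_per_calf * avg, 2)


def first_calving_wean_rate(first_year_calves: int, n_retained: int) -> float:
    """Percent of retained heifers weaning a calf at first calving,
    rounded to an integer percent."""
    if n_retained <= 0:
        raise ZeroDivisionError("no retained daughters")
    return round_half_up(100.0 * first_year_calves / n_retained, 0)


# -- full cohort table -------------------------------------------------------

def build_cohort_table(herd: HerdBook, strata: list[SireStratum],
                       heifer_birth_years: list[int],
                       calving_years: list[int] | None = None,
                       use_rounded_average: bool = True) -> pd.DataFrame:
    """Per (heifer birth-year, sire stratum) retention and productivity.

    ``heifer_birth_years`` are breeding years of the daughter crops;
    ``calving_years`` the breeding years in which their calves are counted
    (default: every later year present in the herd book). A ``Total`` row
    per birth year aggregates the strata.
    """
    animals = herd.animals
    calves = herd.calves
    if calving_years is None:
        calving_years = sorted(
            int(y) for y in calves["year"].dropna().unique()
            if y > min(heifer_birth_years))
    rows = []
    for birth_year in heifer_birth_years:
        crop = calves[(calves["year"] == birth_year) & (calves["sex"] == "F")]
        totals = {y: 0 for y in calving_years}
        total_row = {"birth_year": birth_year, "stratum": "Total",
                     "avg_bpi": np.nan, "n_sires": 0, "n_daughters_sired": 0,
                     "n_daughters_retained": 0}
        for stratum in strata:
            members = set(stratum.members)
            daughters = crop[crop["assigned_sire_id"].isin(members)]
            retained = daughters[daughters["retained"]]
            rids = set(retained["animal_id"])
            grand = calves[calves["dam_id"].isin(rids)
                           & calves["year"].isin(calving_years)]
            by_year = grand.groupby("year").size()
            weaned = grand[grand["weaning_weight"].notna()]
            n_weaned = len(weaned)
            n_sires = len(stratum.members)
            last_year = max(calving_years) if calving_years else None
            last_calvers = (grand[grand["year"] == last_year]["dam_id"].nunique()
                            if last_year is not None else 0)
            row = {
                "birth_year": birth_year, "stratum": stratum.label,
                "avg_bpi": round_half_up(stratum.avg_bpi, 2),
                "n_sires": n_sires,
                "n_daughters_sired": len(daughters),
                "n_daughters_retained": len(rids),
            }
            for y in calving_years:
                row[f"calves_{y}"] = int(by_year.get(y, 0))
                totals[y] += int(by_year.get(y, 0))
            row["pct_remaining"] = (
                pct_remaining(last_calvers, len(rids)) if rids else 0.0)
            row["total_calves_weaned"] = n_weaned
            row["avg_grandcalves_per_sire"] = (
                grandcalves_per_sire(n_weaned, n_sires) if n_sires else 0.0)
            row["avg_ww_per_calf"] = (
                round_half_up(float(weaned["weaning_weight"].mean()), 2)
                if n_weaned else 0.0)
            row["total_kg_weaned_per_sire"] = (
                total_kg_weaned_per_sire(
                    row["avg_ww_per_calf"], row["avg_grandcalves_per_sire"],
                    use_rounded_average)
                if n_weaned else 0.0)
            rows.append(row)
            total_row["n_sires"] += n_sires
            total_row["n_daughters_sired"] += len(daughters)
            total_row["n_daughters_retained"] += len(rids)
        for y in calving_years:
            total_row[f"calves_{y}"] = totals[y]
        stratum_rows = [r for r in rows if r["birth_year"] == birth_year
                        and r["stratum"] != "Total"]
        retained_all = total_row["n_daughters_retained"]
        # total % remaining recomputed over all retained daughters together
        all_rids = set()
        for stratum in strata:
            members = set(stratum.members)
            d = crop[crop["assigned_sire_id"].isin(members)]
            all_rids |= set(d[d["retained"]]["animal_id"])
        grand_all = calves[calves["dam_id"].isin(all_rids)
                           & calves["year"].isin(calving_years)]
        last_year = max(calving_years) if calving_years else None
        total_row["pct_remaining"] = (
            pct_remaining(
                grand_all[grand_all["year"] == last_year]["dam_id"].nunique(),
                retained_all)
            if retained_all else 0.0)
        total_row["total_calves_weaned"] = int(
            grand_all["weaning_weight"].notna().sum())
        total_row["avg_grandcalves_per_sire"] = np.nan
        total_row["avg_ww_per_calf"] = np.nan
        total_row["total_kg_weaned_per_sire"] = np.nan
        rows.append(total_row)
        del stratum_rows
    return pd.DataFrame(rows)


def first_cycle_linkage(per_sire: pd.DataFrame,
                        strata: list[SireStratum]) -> pd.DataFrame:
    """Per-stratum OLS R-squared of the percentage of a sire's grand calves
    born in cycle 1 on the percentage of his daughters born in cycle 1.

    ``per_sire`` needs columns sire_id, pct_daughters_cycle1,
    pct_grandcalves_cycle1. Strata with fewer than 3 sires are flagged.
    """
    out = []
    for stratum in strata:
        pts = per_sire[per_sire["sire_id"].isin(stratum.members)].dropna(
            subset=["pct_daughters_cycle1", "pct_grandcalves_cycle1"])
        if len(pts) < 3:
            out.append({"stratum": stratum.label, "n_sires": len(pts),
                        "r_squared": np.nan, "undefined": True})
            continue
        y = pts["pct_grandcalves_cycle1"].to_numpy()
        if np.var(y) == 0:
            r2 = 0.0  # flat response: nothing to explain
        else:
            X = sm.add_constant(pts["pct_daughters_cycle1"].to_numpy())
            r2 = float(sm.OLS(y, X).fit().rsquared)
        out.append({"stratum": stratum.label, "n_sires": len(pts),
                    "r_squared": r2, "undefined": False})
    return pd.DataFrame(out, columns=["stratum", "n_sires", "r_squared",
                                      "undefined"])


def per_sire_first_cycle_shares(herd: HerdBook, cycles: pd.DataFrame,
                                heifer_birth_years: list[int]) -> pd.DataFrame:
    """Per sire: % of daughters born in cycle 1 and % of grand calves born
    in cycle 1 (inputs for the first-cycle linkage regression)."""
    calves = herd.calves.merge(
        cycles[["calf_id", "cycle"]], left_on="animal_id",
        right_on="calf_id", how="left")
    daughters = calves[(calves["sex"] == "F")
                       & calves["year"].isin(heifer_birth_years)
                       & calves["assigned_sire_id"].notna()]
    rows = []
    for sire, d in daughters.groupby("assigned_sire_id"):
        rids = set(d[d["retained"]]["animal_id"])
        grand = calves[calves["dam_id"].isin(rids)]
        rows.append({
            "sire_id": sire,
            "n_daughters": len(d),
            "pct_daughters_cycle1": 100.0 * float((d["cycle"] == 1).mean()),
            "n_grandcalves": len(grand),
            "pct_grandcalves_cycle1": (
                100.0 * float((grand["cycle"] == 1).mean())
                if len(grand) else np.nan),
        })
    return pd.DataFrame(rows, columns=["sire_id", "n_daughters",
                                       "pct_daughters_cycle1", "n_grandcalves",
                                       "pct_grandcalves_cycle1"])
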