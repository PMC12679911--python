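"""Bull Prolificacy Index (BPI) and sire-level summaries.

For a multi-sire breeding group-year with m sires and N sire-verified
calves, a sire with n verified calves scores

    BPI = n / (N / m) = n * m / N

so 1.0 is the equal-share expectation, values above 1 mark prolific bulls
and the index sums to exactly m over the group's sires. The first-cycle
variant substitutes the calves born in the first 21-day calving cycle for
n and N (m unchanged). Sires are stratified by rank into Bottom 25% /
Average 50% / Top 25%, and across-year repeatability is measured by
Spearman rank correlation between use-years with a permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import log, round_half_up
from .herdbook import HerdBook

STRATA_LABELS = ("Bottom25", "Average50", "Top25")


def bpi(n: int, N: int, m: int) -> float:
    """Bull Prolificacy Index n·m/N at full precision."""
    if N <= 0 or m <= 0:
        raise ZeroDivisionError(
            f"BPI undefined for N={N}, m={m} (no matched calves or no sires)"
        )
    if not 0 <= n <= N:
        raise ValueError(f"need 0 <= n <= N, got n={n}, N={N}")
    return n * m / N


def bpi_first_cycle(n_first: int, N_first: int, m: int) -> float:
    """BPI restricted to first-cycle births: same formula on first-cycle
    counts, sire count m unchanged."""
    return bpi(n_first, N_first, m)


def bpi_table(parentage: pd.DataFrame, herd: HerdBook,
              cycles: pd.DataFrame | None = None) -> pd.DataFrame:
    """One BPI record per (sire, group-year) served.

    Only sire-verified calves enter n and N. ``cycles`` (calf_id, cycle)
    adds the first-cycle columns; group-years with no first-cycle calves get
    a flagged NaN first-cycle BPI rather than a silent zero.
    """
    calves = herd.calves[["animal_id", "group", "year"]].rename(
        columns={"animal_id": "calf_id"})
    matched = parentage[parentage["assigned_sire_id"].notna()].merge(
        calves, on="calf_id", how="left")
    if cycles is not None and not cycles.empty:
        matched = matched.merge(cycles[["calf_id", "cycle"]], on="calf_id",
                                how="left")
    else:
        matched["cycle"] = np.nan
    births = {a: d for a, d in
              zip(herd.animals["animal_id"], herd.animals["birth_date"])}
    rows = []
    for (group, year) in herd.group_years():
        roster = herd.candidate_sires(group, year)
        gy = matched[(matched["group"] == group) & (matched["year"] == year)]
        N = len(gy)
        m = len(roster) if roster else gy["assigned_sire_id"].nunique()
        if not roster:
            roster = sorted(gy["assigned_sire_id"].unique())
            log.warning("no roster for group %s year %s; m inferred as %d",
                        group, year, m)
        n_by_sire = gy.groupby("assigned_sire_id").size()
        first = gy[gy["cycle"] == 1]
        N_first = len(first)
        nf_by_sire = first.groupby("assigned_sire_id").size()
        for sire in roster:
            n = int(n_by_sire.get(sire, 0))
            n_first = int(nf_by_sire.get(sire, 0))
            age = (year - births[sire].year) if sire in births else np.nan
            rows.append({
                "sire_id": sire, "group": group, "year": year,
                "n": n, "N": N, "m": m,
                "bpi": bpi(n, N, m) if N > 0 else np.nan,
                "n_first": n_first, "N_first": N_first,
                "bpi_first": (bpi_first_cycle(n_first, N_first, m)
                              if N_first > 0 else np.nan),
                "sire_age": age,
                "undefined": N == 0,
                "first_cycle_undefined": N_first == 0,
            })
    return pd.DataFrame(rows)


def bpi_range_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per group-year descriptive table: sire and calf counts, min/max
    calves per sire and min/max BPI (the published Table-1 shape)."""
    out = []
    for (group, year), gy in records.groupby(["group", "year"]):
        served = gy[gy["n"] > 0]
        out.append({
            "group": group, "year": year, "n_sires": int(gy["m"].iloc[0]),
            "total_calves": int(gy["N"].iloc[0]),
            "min_calves": int(served["n"].min()) if not served.empty else 0,
            "max_calves": int(served["n"].max()) if not served.empty else 0,
            "min_bpi": float(served["bpi"].min()) if not served.empty else np.nan,
            "max_bpi": float(served["bpi"].max()) if not served.empty else np.nan,
        })
    return pd.DataFrame(out).sort_values(["year", "group"]).reset_index(drop=True)


@dataclass
class SireStratum:
    label: str
    avg_bpi: float
    members: list[str]


def stratify_sires(records: pd.DataFrame,
                   by: str = "bpi") -> list[SireStratum]:
    """Rank sires into Bottom 25% / Average 50% / Top 25% by BPI.

    A sire appearing in several group-years enters at its mean BPI.
    Quartile sizes use half-up rounding of n/4 (8 sires -> 2/4/2); ties are
    broken by sire id so the split is deterministic. Fewer than 4 sires
    collapse to a single stratum with a warning.
    """
    per_sire = (records.groupby("sire_id")[by].mean()
                .reset_index()
                .sort_values([by, "sire_id"])
                .reset_index(drop=True))
    n = len(per_sire)
    if n == 0:
        return []
    if n < 4:
        log.warning("only %d sires: single stratum", n)
        return [SireStratum("Average50", float(per_sire[by].mean()),
                            per_sire["sire_id"].tolist())]
    q = max(1, int(round_half_up(n / 4)))
    bottom = per_sire.iloc[:q]
    top = per_sire.iloc[n - q:]
    middle = per_sire.iloc[q:n - q]
    return [
        SireStratum("Bottom25", float(bottom[by].mean()), bottom["sire_id"].tolist()),
        SireStratum("Average50", float(middle[by].mean()), middle["sire_id"].tolist()),
        SireStratum("Top25", float(top[by].mean()), top["sire_id"].tolist()),
    ]


def strata_frame(strata: list[SireStratum]) -> pd.DataFrame:
    rows = [{"stratum": s.label, "avg_bpi": s.avg_bpi, "sire_id": m}
            for s in strata for m in s.members]
    return pd.DataFrame(rows, columns=["stratum", "avg_bpi", "sire_id"])


def repeatability(records: pd.DataFrame, n_permutations: int = 999,
                  rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Spearman correlation of per-sire BPI between use-year 1 and each
    later use-year, with a permutation p-value.

    A sire's use-years are its breeding years in chronological order
    (use-year 1 = first year it served). Pairs with fewer than 3 sires are
    flagged undefined.
    """
    rng = rng or np.random.default_rng(0)
    per = records[records["n"] > 0].copy()
    per["use_year"] = (per.sort_values("year")
                       .groupby("sire_id")["year"]
                       .rank(method="dense").astype(int))
    base = per[per["use_year"] == 1].groupby("sire_id")["bpi"].mean()
    out = []
    for k in sorted(per["use_year"].unique()):
        if k == 1:
            continue
        later = per[per["use_year"] == k].groupby("sire_id")["bpi"].mean()
        common = sorted(set(base.index) & set(later.index))
        if len(common) < 3:
            out.append({"use_year_pair": f"1-{k}", "n_sires": len(common),
                        "rho": np.nan, "p_value": np.nan, "undefined": True})
            continue
        x = base.loc[common].to_numpy()
        y = later.loc[common].to_numpy()
        rho = float(stats.spearmanr(x, y).statistic)
        null = np.empty(n_permutations)
        for i in range(n_permutations):
            null[i] = stats.spearmanr(x, rng.permutation(y)).statistic
        p = float((np.sum(np.abs(null) >= abs(rho)) + 1) / (n_permutations + 1))
        out.append({"use_year_pair": f"1-{k}", "n_sires": len(common),
                    "rho": rho, "p_value": p, "undefined": False})
    return pd.DataFrame(out, columns=["use_year_pair", "n_sires", "rho",
                                      "p_value", "undefined"])


def age_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Descriptive BPI statistics by sire age class {1, 2, >=3}."""
    df = records[records["sire_age"].notna()].copy()
    df["age_class"] = df["sire_age"].map(
        lambda a: "1" if a <= 1 else ("2" if a == 2 else ">=3"))
    out = df.groupby("age_class")["bpi"].agg(
        n="size", mean="mean", sd=lambda v: float(np.std(v, ddof=0)) if len(v) == 1
        else float(np.std(v, ddof=1)), median="median").reset_index()
    order = {"1": 0, "2": 1, ">=3": 2}
    return out.sort_values("age_class", key=lambda s: s.map(order)).reset_index(drop=True)
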