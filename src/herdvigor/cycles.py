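"""21-day calving-cycle assignment and distribution summaries.

Following standardized performance-analysis convention, the first 21-day
calving period of a season opens on the date the 3rd mature cow (3 years
and older) calves. Calves are binned into half-open 21-day cycles from
that start; births before it (early heifers) clamp to cycle 1 with a
flag. Distributions are summarized per breeding group-year against the
recommendation that 60% of the calf crop arrives in the first cycle.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np
import pandas as pd

from ._util import age_in_years, log
from .config import RunConfig
from .herdbook import HerdBook


class SeasonStartUndefined(ValueError):
    """Fewer mature-cow calvings than the configured rank."""


def season_start(calvings: pd.DataFrame, mature_age: int = 3,
                 rank: int = 3) -> _dt.date:
    """Date of the rank-th chronological calving by a mature dam.

    ``calvings`` needs columns calf_id, birth_date, dam_age (dam's whole-year
    age at the calving). Same-day calvings are ordered by calf id.
    """
    mature = calvings[calvings["dam_age"] >= mature_age]
    if len(mature) < rank:
        raise SeasonStartUndefined(
            f"only {len(mature)} mature-cow calvings; need {rank}"
        )
    ordered = mature.sort_values(["birth_date", "calf_id"])
    return ordered["birth_date"].iloc[rank - 1]


def _calvings_frame(calves: pd.DataFrame, dam_births: dict) -> pd.DataFrame:
    rows = calves[["animal_id", "birth_date", "dam_id"]].copy()
    rows["dam_age"] = [
        age_in_years(dam_births[d], b) if d in dam_births else -1
        for d, b in zip(rows["dam_id"], rows["birth_date"])
    ]
    return rows.rename(columns={"animal_id": "calf_id"})


def assign_cycles(herd: HerdBook, config: RunConfig | None = None) -> pd.DataFrame:
    """Cycle assignment for every calf: one row (calf_id, group, year,
    season_start, cycle, clamped).

    The season start is computed per breeding group-year; a group-year
    without enough mature-cow calvings (e.g. an all-heifer group) falls
    back to the herd-wide start for that year, flagged via
    ``herd_wide_start``. Setting ``config.herd_wide_season_start`` uses the
    herd-wide start everywhere.
    """
    config = config or RunConfig()
    dam_births = dict(zip(herd.animals["animal_id"], herd.animals["birth_date"]))
    calves = herd.calves
    out = []
    herd_wide: dict[int, _dt.date] = {}
    for year in sorted(calves["year"].dropna().unique()):
        yr = calves[calves["year"] == year]
        try:
            herd_wide[int(year)] = season_start(
                _calvings_frame(yr, dam_births),
                config.mature_age_years, config.first_cycle_start_rank)
        except SeasonStartUndefined:
            pass
    for (group, year) in herd.group_years():
        gy = calves[(calves["group"] == group) & (calves["year"] == year)]
        used_herd_wide = config.herd_wide_season_start
        if config.herd_wide_season_start:
            start = herd_wide.get(year)
        else:
            try:
                start = season_start(
                    _calvings_frame(gy, dam_births),
                    config.mature_age_years, config.first_cycle_start_rank)
            except SeasonStartUndefined:
                start = herd_wide.get(year)
                used_herd_wide = True
                log.info("group %s year %s: falling back to herd-wide "
                         "season start", group, year)
        if start is None:
            raise SeasonStartUndefined(
                f"season start undefined for year {year}: too few "
                "mature-cow calvings herd-wide"
            )
        for _, calf in gy.iterrows():
            delta = (calf["birth_date"] - start).days
            clamped = delta < 0
            cycle = 1 if clamped else 1 + delta // config.cycle_length_days
            out.append({
                "calf_id": calf["animal_id"], "group": group, "year": year,
                "season_start": start, "cycle": int(cycle),
                "clamped": bool(clamped), "herd_wide_start": used_herd_wide,
            })
    return pd.DataFrame(out, columns=["calf_id", "group", "year",
                                      "season_start", "cycle", "clamped",
                                      "herd_wide_start"])


def cycle_distribution(assignments: pd.DataFrame,
                       benchmark: float = 0.60) -> pd.DataFrame:
    """Per group-year percentage of calves in each cycle plus the
    first-cycle benchmark flag (share of cycle-1 births >= benchmark).
    Percentages sum to 100 within each group-year."""
    if assignments.empty:
        return pd.DataFrame(columns=["group", "year", "cycle", "n",
                                     "percent", "meets_benchmark"])
    out = []
    for (group, year), gy in assignments.groupby(["group", "year"]):
        total = len(gy)
        if total == 0:
            log.warning("group %s year %s empty; omitted", group, year)
            continue
        counts = gy.groupby("cycle").size()
        share1 = counts.get(1, 0) / total
        for cycle in range(1, int(counts.index.max()) + 1):
            n = int(counts.get(cycle, 0))
            out.append({
                "group": group, "year": year, "cycle": cycle, "n": n,
                "percent": 100.0 * n / total,
                "meets_benchmark": bool(share1 >= benchmark),
            })
    return pd.DataFrame(out)


def first_cycle_share(assignments: pd.DataFrame) -> pd.DataFrame:
    """Per group-year fraction of the crop born in the first 21 days."""
    rows = []
    for (group, year), gy in assignments.groupby(["group", "year"]):
        rows.append({
            "group": group, "year": year, "n": len(gy),
            "first_cycle_share": float((gy["cycle"] == 1).mean()),
        })
    return pd.DataFrame(rows)
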