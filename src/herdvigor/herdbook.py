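"""Herd-book container and CSV round-trip.

The herd book is the longitudinal animal registry: one row per animal
(sires, dams and calves alike) with pedigree links, birth dates, breeding
group-year membership for calves, weights and retention/disposal records.
A companion sire-roster table records which sires served which breeding
group in which year — needed both for the sire count m in the prolificacy
index and for the candidate list in parentage testing.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import log, parse_date

#: Canonical herd-book CSV header.
HERDBOOK_COLUMNS = [
    "animal_id", "sex", "birth_date", "dam_id", "true_sire_id",
    "assigned_sire_id", "group", "year", "birth_weight", "weaning_weight",
    "retained", "disposal_year",
]

SIRE_GROUP_COLUMNS = ["sire_id", "group", "year"]


class HerdBookError(ValueError):
    """Malformed herd-book input (missing columns, dangling ids, bad dates)."""


@dataclass
class HerdBook:
    """Validated animal registry.

    Parameters
    ----------
    animals : pandas.DataFrame
        One row per animal with `HERDBOOK_COLUMNS`. ``birth_date`` holds
        ``datetime.date``; id columns hold strings or ``None``; ``group``/
        ``year`` are nullable integers (set for calves born into a breeding
        group-year, absent for founders).
    sire_groups : pandas.DataFrame
        Roster of (sire_id, group, year) service records.
    """

    animals: pd.DataFrame
    sire_groups: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=SIRE_GROUP_COLUMNS)
    )

    def __post_init__(self) -> None:
        self.animals = _normalise_animals(self.animals)
        self.sire_groups = _normalise_roster(self.sire_groups)
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        df = self.animals
        if df["animal_id"].duplicated().any():
            dups = df.loc[df["animal_id"].duplicated(), "animal_id"].tolist()
            raise HerdBookError(f"duplicate animal ids: {dups}")
        ids = set(df["animal_id"])
        births = dict(zip(df["animal_id"], df["birth_date"]))
        for col in ("dam_id", "true_sire_id", "assigned_sire_id"):
            for idx, parent in df[col].items():
                if parent is None:
                    continue
                if parent not in ids:
                    raise HerdBookError(
                        f"row {idx}: {col} '{parent}' not in herd book"
                    )
                if births[parent] >= df.at[idx, "birth_date"]:
                    raise HerdBookError(
                        f"row {idx}: calf born {df.at[idx, 'birth_date']} "
                        f"on/before its {col} '{parent}' ({births[parent]})"
                    )
        extra = set(self.sire_groups["sire_id"]) - ids
        if extra:
            raise HerdBookError(f"sire roster references unknown sires: {sorted(extra)}")

    # -- convenience views ----------------------------------------------
    @property
    def calves(self) -> pd.DataFrame:
        """Animals born into a breeding group-year (the calf crops)."""
        return self.animals[self.animals["year"].notna()]

    def birth_date_of(self, animal_id: str) -> _dt.date:
        row = self.animals.loc[self.animals["animal_id"] == animal_id]
        if row.empty:
            raise KeyError(animal_id)
        return row["birth_date"].iloc[0]

    def candidate_sires(self, group: int, year: int) -> list[str]:
        r = self.sire_groups
        sel = r[(r["group"] == group) & (r["year"] == year)]
        return sorted(sel["sire_id"].tolist())

    def group_years(self) -> list[tuple[int, int]]:
        gy = self.calves[["group", "year"]].drop_duplicates()
        return sorted((int(g), int(y)) for g, y in gy.itertuples(index=False))


def _normalise_animals(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in HERDBOOK_COLUMNS if c not in df.columns]
    if missing:
        raise HerdBookError(f"herd book missing columns: {missing}")
    df = df[HERDBOOK_COLUMNS].copy().reset_index(drop=True)
    df["animal_id"] = df["animal_id"].astype(str)
    df["sex"] = df["sex"].astype(str).str.upper()
    bad_sex = ~df["sex"].isin(["F", "M"])
    if bad_sex.any():
        raise HerdBookError(
            f"rows {list(df.index[bad_sex])}: sex must be F or M"
        )
    try:
        df["birth_date"] = df["birth_date"].map(parse_date)
    except ValueError as exc:
        raise HerdBookError(f"unparseable birth_date: {exc}") from exc
    for col in ("dam_id", "true_sire_id", "assigned_sire_id"):
        df[col] = df[col].map(
            lambda v: None if v is None or (isinstance(v, float) and np.isnan(v))
            or str(v) in ("", "nan", "NA", "None") else str(v)
        )
    for col in ("group", "year", "disposal_year"):
        df[col] = pd.array(
            [None if pd.isna(v) else int(v) for v in df[col]], dtype="Int64"
        )
    for col in ("birth_weight", "weaning_weight"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["retained"] = df["retained"].map(
        lambda v: bool(v) if not pd.isna(v) and str(v) not in ("", "False", "false", "0")
        else False
    )
    return df


def _normalise_roster(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SIRE_GROUP_COLUMNS if c not in df.columns]
    if missing:
        raise HerdBookError(f"sire roster missing columns: {missing}")
    df = df[SIRE_GROUP_COLUMNS].copy().reset_index(drop=True)
    df["sire_id"] = df["sire_id"].astype(str)
    df["group"] = df["group"].astype(int)
    df["year"] = df["year"].astype(int)
    return df


# -- CSV round-trip -------------------------------------------------------

def read_herdbook(path: str | Path, sire_groups_path: str | Path | None = None) -> HerdBook:
    """Read a herd-book CSV (and optional sire-roster CSV)."""
    df = pd.read_csv(path, dtype={"animal_id": str, "dam_id": str,
                                  "true_sire_id": str, "assigned_sire_id": str})
    roster = (
        pd.read_csv(sire_groups_path, dtype={"sire_id": str})
        if sire_groups_path is not None
        else pd.DataFrame(columns=SIRE_GROUP_COLUMNS)
    )
    hb = HerdBook(df, roster)
    log.info("read herd book: %d animals, %d roster rows",
             len(hb.animals), len(hb.sire_groups))
    return hb


def write_herdbook(herd: HerdBook, path: str | Path,
                   sire_groups_path: str | Path | None = None) -> None:
    out = herd.animals.copy()
    out["birth_date"] = out["birth_date"].map(lambda d: d.isoformat())
    out["retained"] = out["retained"].map(lambda v: "true" if v else "false")
    out.to_csv(path, index=False)
    if sire_groups_path is not None:
        herd.sire_groups.to_csv(sire_groups_path, index=False)
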