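"""Genomic vigor score (retained heterozygosity) and breed-composition algebra.

An animal's genomic breed composition (GBC) is a vector of fractional
ancestries over up to 13 recognized beef/dairy breeds plus an
"indeterminate" remainder, summing to 1. The vigor score

    VS = 1 - sum_i P_i^2

is the probability that two ancestry draws come from different breeds —
a proxy for retained heterosis. It is 0 for a purebred and approaches
1 - 1/k for an even k-breed composite: a (0.5, 0.25, 0.25) cross scores
0.625.

Dams without their own genomic test are reconstructed from a tested calf
and sire via the Mendelian mean inversion dam = 2*calf - sire (component-
wise), with negative components clamped to zero and the vector
renormalized (flagged) when the averaged-GBC approximation breaks down.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: The 13 breeds the commercial panel recognizes, plus the indeterminate rest.
RECOGNIZED_BREEDS = [
    "Angus", "BrownSwiss", "Charolais", "Galloway", "Gelbvieh", "Hereford",
    "Holstein", "Jersey", "Limousin", "MaineAnjou", "Salers", "Shorthorn",
    "Simmental",
]
INDETERMINATE = "indeterminate"

_SUM_TOL = 1e-9


class CompositionError(ValueError):
    pass


def _as_fractions(composition) -> np.ndarray:
    if isinstance(composition, dict):
        vals = np.asarray(list(composition.values()), dtype=float)
    elif isinstance(composition, pd.Series):
        vals = composition.to_numpy(dtype=float)
    else:
        vals = np.asarray(composition, dtype=float)
    if (vals < -_SUM_TOL).any() or (vals > 1 + _SUM_TOL).any():
        raise CompositionError(f"breed fractions outside [0, 1]: {vals}")
    return vals


def vigor_score(composition, include_indeterminate: bool = True) -> float:
    """Retained heterozygosity 1 - sum(P_i^2) of a breed-composition vector.

    Parameters
    ----------
    composition : mapping / Series / array of breed fractions summing to 1.
        May include an ``indeterminate`` component.
    include_indeterminate : bool
        If True (default) the indeterminate fraction enters the sum as one
        pseudo-breed component. If False and the input is a mapping/Series
        with an ``indeterminate`` key, that component is dropped and the
        named fractions renormalized first.
    """
    if not include_indeterminate and isinstance(composition, (dict, pd.Series)):
        items = dict(composition)
        items.pop(INDETERMINATE, None)
        vals = _as_fractions(items)
        total = vals.sum()
        if total <= 0:
            raise CompositionError("composition is entirely indeterminate")
        vals = vals / total
    else:
        vals = _as_fractions(composition)
        if abs(vals.sum() - 1.0) > 1e-6:
            raise CompositionError(
                f"breed fractions sum to {vals.sum():.6f}, expected 1"
            )
        vals = vals / vals.sum()
    return float(1.0 - np.sum(vals ** 2))


@dataclass
class DamInference:
    """Result of back-calculating a dam's GBC from calf and sire."""

    fractions: pd.Series
    clamped: bool


def infer_dam_composition(calf: pd.Series, sire: pd.Series) -> DamInference:
    """Invert the parental-mean rule: dam = 2*calf - sire, component-wise.

    Negative components (possible because tested calves only approximate
    the parental mean) are clamped to 0 and the vector renormalized; the
    repair is reported via ``clamped``.
    """
    if list(calf.index) != list(sire.index):
        raise CompositionError(
            "calf and sire compositions are over different breed sets"
        )
    raw = 2.0 * calf.astype(float) - sire.astype(float)
    clamped = bool((raw < -_SUM_TOL).any())
    fixed = raw.clip(lower=0.0)
    total = fixed.sum()
    if total <= 0:
        raise CompositionError("inferred dam composition is degenerate (all zero)")
    return DamInference(fractions=fixed / total, clamped=clamped)


def vs_bin_label(score: float, width: float = 0.10) -> str:
    """Half-open decile-style bin label, top bin closed (e.g. ``0.70-0.80``)."""
    if width <= 0:
        raise ValueError("bin width must be positive")
    # guard against 0.70/0.10 = 6.999... landing in the bin below
    idx = int(np.floor(score / width + 1e-9))
    idx = min(idx, int(round(1.0 / width)) - 1)
    edge = idx * width
    return f"{edge:.2f}-{edge + width:.2f}"


def bin_by_vigor(records: pd.DataFrame, width: float = 0.10,
                 score_col: str = "vigor_score") -> pd.DataFrame:
    """Group animals into half-open vigor-score bins [a, a+width).

    ``records`` needs a vigor-score column; any breed-fraction columns
    present are averaged per bin. Returns one row per non-empty bin with
    ``vs_bin``, ``n`` and per-breed means.
    """
    if records.empty:
        return pd.DataFrame(columns=["vs_bin", "n"])
    df = records.copy()
    df["vs_bin"] = df[score_col].map(lambda s: vs_bin_label(s, width))
    numeric = [c for c in df.columns
               if c not in ("vs_bin",) and pd.api.types.is_numeric_dtype(df[c])]
    out = df.groupby("vs_bin", as_index=False).agg(
        n=(score_col, "size"), **{c: (c, "mean") for c in numeric}
    )
    return out.sort_values("vs_bin").reset_index(drop=True)


def composition_table_scores(compositions: pd.DataFrame,
                             include_indeterminate: bool = True) -> pd.DataFrame:
    """Vigor score + bin label for every row of a composition table.

    ``compositions`` has ``animal_id`` plus one column per breed (and
    optionally ``indeterminate``).
    """
    breed_cols = [c for c in compositions.columns if c != "animal_id"]
    scores = [
        vigor_score(row[breed_cols], include_indeterminate=include_indeterminate)
        for _, row in compositions.iterrows()
    ]
    out = compositions[["animal_id"]].copy()
    out["vigor_score"] = scores
    out["vs_bin"] = [vs_bin_label(s) for s in scores]
    return out
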