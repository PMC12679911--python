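"""SNP-exclusion sire verification.

Each calf is tested against the candidate sires of its dam's breeding
group-year by counting opposing homozygotes — loci where calf and
candidate are homozygous for different alleles, which is Mendelian-
impossible without a genotyping error. Candidates with at most
``max_mismatches`` opposing homozygotes on the base panel are compatible;
a unique compatible candidate is the assigned sire, ambiguity triggers a
re-test on an extended panel, and anything unresolved is classified
``no_sire_match``. Dam genotypes are never used: dams are known from herd
records, only sires need DNA confirmation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import log
from .config import RunConfig
from .genotypes import GenotypePanel
from .herdbook import HerdBook

STATUS_MATCHED = "matched"
STATUS_NO_MATCH = "no_sire_match"
STATUS_EXTENDED = "ambiguous_resolved_by_extension"


@dataclass
class ParentageResult:
    calf_id: str
    assigned_sire_id: str | None
    n_candidates: int
    opposing_homozygote_counts: dict[str, int] = field(default_factory=dict)
    panel_size_used: int = 0
    status: str = STATUS_NO_MATCH

    def __post_init__(self) -> None:
        if (self.status == STATUS_NO_MATCH) != (self.assigned_sire_id is None):
            raise ValueError(
                "no_sire_match status must coincide with an absent sire"
            )


def count_opposing_homozygotes(calf: np.ndarray, candidate: np.ndarray) -> int:
    """Loci where one animal carries 0 and the other 2 copies of the
    reference allele; missing calls never count."""
    calf = np.asarray(calf)
    candidate = np.asarray(candidate)
    if calf.shape != candidate.shape:
        raise ValueError(
            f"genotype vectors differ in length: {calf.shape} vs {candidate.shape}"
        )
    return int(np.count_nonzero(
        ((calf == 0) & (candidate == 2)) | ((calf == 2) & (candidate == 0))
    ))


def assign_sire(calf_id: str, candidates: list[str], panel: GenotypePanel,
                base_panel_size: int = 100, extension_size: int = 0,
                max_mismatches: int = 1) -> ParentageResult:
    """Exclusion test of one calf against its candidate sires.

    The base panel is the first ``base_panel_size`` loci in panel order and
    the extension the next ``extension_size`` — a deterministic convention.
    Ties after extension are broken by fewest mismatches; a residual tie is
    a ``no_sire_match``.
    """
    if not candidates:
        raise ValueError(f"calf {calf_id}: empty candidate sire list")
    calf_g = panel.get(calf_id)
    n_loci = len(panel.loci)
    base = min(base_panel_size, n_loci)
    counts = {
        c: count_opposing_homozygotes(calf_g[:base], panel.get(c)[:base])
        for c in sorted(candidates)
    }
    compatible = [c for c, k in counts.items() if k <= max_mismatches]
    if len(compatible) == 1:
        return ParentageResult(calf_id, compatible[0], len(candidates),
                               counts, base, STATUS_MATCHED)
    if not compatible:
        return ParentageResult(calf_id, None, len(candidates), counts, base,
                               STATUS_NO_MATCH)
    # ambiguous on the base panel: extend and re-test the survivors
    extended = min(base + extension_size, n_loci)
    ext_counts = {
        c: count_opposing_homozygotes(calf_g[:extended], panel.get(c)[:extended])
        for c in compatible
    }
    counts.update(ext_counts)
    still = [c for c in compatible if ext_counts[c] <= max_mismatches]
    pool = still or compatible
    best = min(ext_counts[c] for c in pool)
    winners = [c for c in pool if ext_counts[c] == best]
    if len(still) == 1:
        return ParentageResult(calf_id, still[0], len(candidates), counts,
                               extended, STATUS_EXTENDED)
    if len(winners) == 1 and still:
        return ParentageResult(calf_id, winners[0], len(candidates), counts,
                               extended, STATUS_EXTENDED)
    return ParentageResult(calf_id, None, len(candidates), counts, extended,
                           STATUS_NO_MATCH)


def verify_parentage(herd: HerdBook, panel: GenotypePanel,
                     config: RunConfig | None = None) -> pd.DataFrame:
    """Run sire verification over every genotyped calf of a herd book.

    Candidates come from the sire roster of the calf's breeding group-year.
    Returns one row per tested calf mirroring ``ParentageResult``.
    """
    config = config or RunConfig()
    rows = []
    for _, calf in herd.calves.iterrows():
        cid = str(calf["animal_id"])
        if cid not in panel:
            continue
        candidates = [c for c in
                      herd.candidate_sires(int(calf["group"]), int(calf["year"]))
                      if c in panel]
        if not candidates:
            log.warning("calf %s: no genotyped candidate sires", cid)
            continue
        res = assign_sire(cid, candidates, panel,
                          base_panel_size=config.base_panel_size,
                          extension_size=config.extension_size,
                          max_mismatches=config.max_mismatches)
        rows.append({
            "calf_id": res.calf_id,
            "assigned_sire_id": res.assigned_sire_id,
            "n_candidates": res.n_candidates,
            "min_opposing_homozygotes": min(
                res.opposing_homozygote_counts.values()),
            "panel_size_used": res.panel_size_used,
            "status": res.status,
        })
        if res.status == STATUS_NO_MATCH:
            log.info("calf %s: no sire match among %d candidates",
                     cid, res.n_candidates)
    return pd.DataFrame(rows, columns=[
        "calf_id", "assigned_sire_id", "n_candidates",
        "min_opposing_homozygotes", "panel_size_used", "status",
    ])


def apply_assignments(herd: HerdBook, parentage: pd.DataFrame) -> HerdBook:
    """Copy DNA-assigned sires into the herd book's assigned_sire_id."""
    animals = herd.animals.copy()
    assigned = dict(zip(parentage["calf_id"], parentage["assigned_sire_id"]))
    animals["assigned_sire_id"] = [
        assigned.get(a, cur) if not pd.isna(assigned.get(a, cur)) else None
        for a, cur in zip(animals["animal_id"], animals["assigned_sire_id"])
    ]
    return HerdBook(animals, herd.sire_groups)


def verification_summary(results: pd.DataFrame | list[ParentageResult]
                         ) -> tuple[int, int, int]:
    """(tested, matched, unmatched) counts; matched + unmatched = tested."""
    if isinstance(results, pd.DataFrame):
        if results.empty:
            return (0, 0, 0)
        matched = int(results["assigned_sire_id"].notna().sum())
        tested = len(results)
    else:
        tested = len(results)
        matched = sum(r.assigned_sire_id is not None for r in results)
    return (tested, matched, tested - matched)


def exclusion_probability(freqs: np.ndarray) -> float:
    """Closed-form probability that a random non-sire shows zero opposing
    homozygotes with a random calf across the panel: prod(1 - 2 p^2 q^2)
    under Hardy-Weinberg at reference-allele frequencies ``freqs``."""
    p = np.asarray(freqs, dtype=float)
    q = 1.0 - p
    return float(np.prod(1.0 - 2.0 * (p ** 2) * (q ** 2)))
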