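"""Biallelic SNP genotype container with matrix-TSV and PED/MAP round-trip.

Genotypes are stored as copies of the reference allele (0/1/2), with -1 for
missing calls — the coding used throughout the parentage stage. Two on-disk
dialects are accepted: a plain animals x loci TSV, and a PLINK-style
PED/MAP pair with A/B allele letters (0 = missing).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import log

MISSING = -1


class GenotypeFormatError(ValueError):
    pass


@dataclass
class GenotypePanel:
    """SNP calls for a set of animals over a shared locus panel."""

    animals: list[str]
    loci: list[str]
    calls: np.ndarray  # (n_animals, n_loci) int8; 0/1/2 or -1 missing

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.animals), len(self.loci)):
            raise GenotypeFormatError(
                f"call matrix shape {self.calls.shape} does not match "
                f"{len(self.animals)} animals x {len(self.loci)} loci"
            )
        bad = ~np.isin(self.calls, [0, 1, 2, MISSING])
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeFormatError(
                f"genotype {self.calls[i, j]} at ({self.animals[i]}, "
                f"{self.loci[j]}) outside {{0,1,2,missing}}"
            )
        self._index = {a: i for i, a in enumerate(self.animals)}
        for animal, rate in zip(self.animals, self.missing_rate()):
            if rate == 1.0:
                log.warning("animal %s has no genotype calls", animal)

    @property
    def shape(self) -> tuple[int, int]:
        return self.calls.shape

    def __contains__(self, animal_id: str) -> bool:
        return animal_id in self._index

    def get(self, animal_id: str) -> np.ndarray:
        return self.calls[self._index[animal_id]]

    def missing_rate(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=1)

    def allele_frequencies(self) -> np.ndarray:
        """Reference-allele frequency per locus over non-missing calls."""
        obs = np.where(self.calls == MISSING, np.nan, self.calls.astype(float))
        with np.errstate(invalid="ignore"):
            return np.nanmean(obs, axis=0) / 2.0

    def subset_loci(self, loci_idx) -> "GenotypePanel":
        idx = np.asarray(loci_idx)
        return GenotypePanel(
            list(self.animals), [self.loci[i] for i in idx], self.calls[:, idx]
        )


# -- IO ---------------------------------------------------------------------

def read_genotypes(path: str | Path, dialect: str = "matrix-tsv",
                   map_path: str | Path | None = None) -> GenotypePanel:
    """Read genotypes from ``matrix-tsv`` or ``ped-map`` files.

    For ``ped-map``, ``path`` is the .ped file and ``map_path`` the .map
    (defaults to ``path`` with a .map suffix).
    """
    if dialect == "matrix-tsv":
        return _read_matrix_tsv(path)
    if dialect == "ped-map":
        map_path = map_path or Path(path).with_suffix(".map")
        return _read_ped_map(path, map_path)
    raise GenotypeFormatError(f"unknown genotype dialect: {dialect}")


def _read_matrix_tsv(path: str | Path) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", index_col=0)
    calls = df.to_numpy(dtype=float)
    calls = np.where(np.isnan(calls), MISSING, calls)
    if not np.isin(calls, [0, 1, 2, MISSING]).all():
        raise GenotypeFormatError(f"{path}: genotype codes outside {{0,1,2,NA}}")
    return GenotypePanel(
        [str(a) for a in df.index], [str(c) for c in df.columns],
        calls.astype(np.int8),
    )


def write_matrix_tsv(panel: GenotypePanel, path: str | Path) -> None:
    df = pd.DataFrame(
        panel.calls.astype(float), index=panel.animals, columns=panel.loci
    ).replace(MISSING, np.nan)
    df.to_csv(path, sep="\t", na_rep="NA", index_label="animal_id")


def _read_ped_map(ped_path: str | Path, map_path: str | Path) -> GenotypePanel:
    mapdf = pd.read_csv(map_path, sep=r"\s+", header=None,
                        names=["chrom", "locus", "cm", "pos"])
    loci = [str(x) for x in mapdf["locus"]]
    animals: list[str] = []
    rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * len(loci):
                raise GenotypeFormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * len(loci)} fields, "
                    f"got {len(fields)}"
                )
            animals.append(fields[1])
            alleles = fields[6:]
            row = np.empty(len(loci), dtype=np.int8)
            for j in range(len(loci)):
                a1, a2 = alleles[2 * j], alleles[2 * j + 1]
                if a1 == "0" or a2 == "0":
                    row[j] = MISSING
                else:
                    for a in (a1, a2):
                        if a not in ("A", "B"):
                            raise GenotypeFormatError(
                                f"{ped_path}:{lineno}: allele '{a}' not in {{A,B,0}}"
                            )
                    row[j] = (a1 == "A") + (a2 == "A")
            rows.append(row)
    return GenotypePanel(animals, loci, np.array(rows, dtype=np.int8))


def write_ped_map(panel: GenotypePanel, ped_path: str | Path,
                  map_path: str | Path) -> None:
    with open(map_path, "w") as fh:
        for j, locus in enumerate(panel.loci):
            fh.write(f"1 {locus} 0 {j + 1}\n")
    coding = {2: "A A", 1: "A B", 0: "B B", MISSING: "0 0"}
    with open(ped_path, "w") as fh:
        for i, animal in enumerate(panel.animals):
            geno = " ".join(coding[int(g)] for g in panel.calls[i])
            fh.write(f"FAM {animal} 0 0 0 -9 {geno}\n")
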