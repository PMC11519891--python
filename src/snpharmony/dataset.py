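"""In-memory genotype dataset: samples x SNPs call matrix plus sidecars.

Calls are stored as a numpy array of 2-character strings (``"AG"``,
``"AB"``, ``"00"``), one character per allele, ``"00"`` meaning missing.
This keeps the matrix compact, vectorizable and trivially serializable
while preserving heterozygote allele order (which PLINK text and Illumina
reports carry, and conversion preserves).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .strand import MISSING, Coding

MISSING_CELL = MISSING + MISSING  # "00"


@dataclass(frozen=True)
class SampleInfo:
    """PED columns 1-6: family/within-family IDs plus pedigree stubs."""

    fid: str
    iid: str
    father: str = "0"
    mother: str = "0"
    sex: str = "0"
    phenotype: str = "-9"

    @property
    def key(self) -> tuple[str, str]:
        return (self.fid, self.iid)


@dataclass(frozen=True)
class SnpInfo:
    """Per-SNP sidecar: name, map position and (optionally) allele pair.

    ``allele1``/``allele2`` follow BIM semantics: "0" when unknown (e.g.
    monomorphic or read from PED text, which carries no allele catalogue).
    """

    name: str
    chromosome: str = "0"
    position: int = 0
    allele1: str = "0"
    allele2: str = "0"


@dataclass
class GenotypeDataset:
    samples: list[SampleInfo]
    snps: list[SnpInfo]
    calls: np.ndarray  # (n_samples, n_snps), dtype U2
    coding: Coding | None = None
    assembly: str | None = None
    chip_name: str | None = None
    source: str | None = None  # dataset name; merged sets carry per-sample origins
    sample_origins: list[str] | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype="U2")
        if self.calls.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"call matrix shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs")
        names = [s.name for s in self.snps]
        if len(set(names)) != len(names):
            raise ValueError("SNP names must be unique within a dataset")
        if self.sample_origins is not None and \
                len(self.sample_origins) != len(self.samples):
            raise ValueError("sample_origins length mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp_index(self) -> dict[str, int]:
        return {s.name: j for j, s in enumerate(self.snps)}

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING_CELL

    def n_missing_per_sample(self) -> np.ndarray:
        return self.missing_mask().sum(axis=1)

    def origin_of(self, i: int) -> str:
        if self.sample_origins is not None:
            return self.sample_origins[i]
        return self.source or ""

    def copy(self) -> "GenotypeDataset":
        return replace(self, samples=list(self.samples), snps=list(self.snps),
                       calls=self.calls.copy(),
                       sample_origins=(list(self.sample_origins)
                                       if self.sample_origins else None))


def sorted_cell(cell: str) -> str:
    a, b = cell[0], cell[1]
    return cell if a <= b else b + a


def calls_equal(a: np.ndarray, b: np.ndarray,
                ignore_het_order: bool = False) -> bool:
    """Matrix equality; optionally up to heterozygote allele order (the
    PLINK 2-bit encoding cannot represent order)."""
    a = np.asarray(a, dtype="U2")
    b = np.asarray(b, dtype="U2")
    if a.shape != b.shape:
        return False
    if not ignore_het_order:
        return bool(np.array_equal(a, b))
    norm = np.vectorize(sorted_cell)
    return bool(np.array_equal(norm(a), norm(b)))
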