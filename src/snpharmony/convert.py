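"""Dataset-level coding operations: inferring a dataset's source coding,
converting a whole dataset to Illumina TOP, and remapping TOP-coded
datasets onto another assembly.

Coding inference scores each candidate coding by concordance — the
fraction of non-missing calls whose alleles are consistent with the
registry's expectation under that coding — and accepts the unique coding
at or above a threshold (default 0.99, tolerating genotyping error).
Ties (typically TOP vs forward when every SNP sits on the same strand)
are broken only by discriminating SNPs, whose expected allele sets differ
between the tied codings; without discriminating evidence the tie is
reported and an explicit override is required.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .dataset import MISSING_CELL, GenotypeDataset, SnpInfo
from .errors import (
    CodingMismatchError,
    SnpHarmonyError,
    UnrecognizedCodingError,
    UnresolvableStrandError,
)
from .registry import Registry, UNMAPPED_CHROM, UNMAPPED_POS, Variant
from .strand import (
    Coding,
    GenotypeCall,
    StrandRelation,
    complement,
    convert_genotype,
    is_ambiguous,
)

logger = logging.getLogger(__name__)

DEFAULT_CONCORDANCE_THRESHOLD = 0.99


def _expected_alleles(variant: Variant, coding: Coding,
                      assembly: str | None) -> frozenset | None:
    """Allele symbols a non-missing call may use at this SNP under a
    coding; ``None`` when the registry cannot say (undefined, excluded
    from that coding's concordance denominator)."""
    if coding is Coding.ILLUMINA_AB:
        return frozenset("AB")
    if coding is Coding.ILLUMINA_TOP:
        return variant.illumina_top.as_set
    if assembly is None:
        return None
    loc = variant.location(assembly, source=coding.location_source)
    if loc is None:
        return None
    if loc.illumina_forward is not None:
        return loc.illumina_forward.as_set
    if loc.strand_relation is StrandRelation.SAME:
        return variant.illumina_top.as_set
    if loc.strand_relation is StrandRelation.OPPOSITE:
        return frozenset(complement(b) for b in variant.illumina_top.as_set)
    return None


@dataclass
class InferenceResult:
    coding: Coding | None
    concordance: dict[Coding, float | None]
    ties: tuple[Coding, ...] = ()
    n_calls: int = 0

    @property
    def is_tie(self) -> bool:
        return self.coding is None and len(self.ties) > 1


def infer_coding(dataset: GenotypeDataset, registry: Registry,
                 threshold: float = DEFAULT_CONCORDANCE_THRESHOLD,
                 ) -> InferenceResult:
    """Infer the genotype coding of ``dataset`` against the registry."""
    codings = list(Coding)
    consistent = {c: 0 for c in codings}
    total = {c: 0 for c in codings}
    per_snp_expected: list[dict[Coding, frozenset | None]] = []
    any_calls = False

    columns = []
    for j, snp in enumerate(dataset.snps):
        variant = registry.resolve(snp.name, dataset.chip_name)
        if variant is None:
            logger.warning("infer_coding: SNP %s not in registry; ignored",
                           snp.name)
            per_snp_expected.append({c: None for c in codings})
            columns.append(None)
            continue
        expected = {c: _expected_alleles(variant, c, dataset.assembly)
                    for c in codings}
        per_snp_expected.append(expected)
        cells, counts = np.unique(dataset.calls[:, j], return_counts=True)
        col = [(set(cell), int(n)) for cell, n in zip(cells, counts)
               if cell != MISSING_CELL]
        columns.append(col)
        for symbols, n in col:
            any_calls = True
            for c in codings:
                if expected[c] is None:
                    continue
                total[c] += n
                if symbols <= expected[c]:
                    consistent[c] += n

    if not any_calls:
        raise SnpHarmonyError("infer_coding requires at least one non-missing call")

    concordance: dict[Coding, float | None] = {
        c: (consistent[c] / total[c] if total[c] else None) for c in codings}
    winners = [c for c in codings
               if concordance[c] is not None and concordance[c] >= threshold]
    n_calls = max(total.values())

    if not winners:
        raise UnrecognizedCodingError(
            "no coding reaches concordance threshold "
            f"{threshold}: " + ", ".join(
                f"{c.value}={concordance[c]:.3f}" if concordance[c] is not None
                else f"{c.value}=n/a" for c in codings),
            concordance={c.value: concordance[c] for c in codings})
    if len(winners) == 1:
        return InferenceResult(winners[0], concordance, n_calls=n_calls)

    # tie-break on discriminating SNPs only
    disc = [j for j, expected in enumerate(per_snp_expected)
            if len({expected[c] for c in winners
                    if expected[c] is not None}) > 1]
    if disc:
        restricted = {c: [0, 0] for c in winners}
        for j in disc:
            if columns[j] is None:
                continue
            for symbols, n in columns[j]:
                for c in winners:
                    exp = per_snp_expected[j][c]
                    if exp is None:
                        continue
                    restricted[c][1] += n
                    if symbols <= exp:
                        restricted[c][0] += n
        scores = {c: (k / t if t else -1.0) for c, (k, t) in restricted.items()}
        best = max(scores.values())
        leaders = [c for c in winners if scores[c] == best]
        if len(leaders) == 1:
            return InferenceResult(leaders[0], concordance, n_calls=n_calls)
        winners = leaders
    return InferenceResult(None, concordance, ties=tuple(winners),
                           n_calls=n_calls)


@dataclass(frozen=True)
class ConversionAction:
    """One row of a conversion report."""

    snp: str
    action: str  # identity | ab-mapped | complemented | excluded-ambiguous | mismatch


def convert_dataset(dataset: GenotypeDataset, registry: Registry,
                    coding: Coding | None = None,
                    on_unresolvable: str = "exclude",
                    ) -> tuple[GenotypeDataset, list[ConversionAction]]:
    """Convert every call into Illumina TOP; returns the converted dataset
    and a per-SNP action report.

    Ambiguous SNPs in forward coding with unknown strand relation cannot
    be converted; following the FAO guideline they are excluded
    (``on_unresolvable="exclude"``, the default) or raised on
    (``"error"``).  A call outside the expected allele set raises
    :class:`CodingMismatchError`.
    """
    coding = Coding(coding or dataset.coding)
    if coding is None:
        raise ValueError("dataset coding unknown; run infer_coding first")
    if on_unresolvable not in ("exclude", "error"):
        raise ValueError("on_unresolvable must be 'exclude' or 'error'")

    keep: list[int] = []
    new_snps: list[SnpInfo] = []
    columns: list[np.ndarray] = []
    report: list[ConversionAction] = []
    for j, snp in enumerate(dataset.snps):
        variant = registry.resolve(snp.name, dataset.chip_name)
        if variant is None:
            raise SnpHarmonyError(f"SNP {snp.name} not found in registry")
        column = dataset.calls[:, j]
        mapping: dict[str, str] = {}
        complemented = False
        try:
            for cell in np.unique(column):
                out = convert_genotype(GenotypeCall(cell[0], cell[1]),
                                       coding, variant, dataset.assembly)
                mapping[cell] = out.allele1 + out.allele2
                if (coding.is_forward and cell != MISSING_CELL
                        and mapping[cell] != cell):
                    complemented = True
        except UnresolvableStrandError:
            if on_unresolvable == "error":
                raise
            report.append(ConversionAction(snp.name, "excluded-ambiguous"))
            logger.warning("excluding ambiguous SNP %s (unknown strand)",
                           snp.name)
            continue
        except CodingMismatchError:
            report.append(ConversionAction(snp.name, "mismatch"))
            raise
        if coding is Coding.ILLUMINA_AB:
            action = "ab-mapped"
        elif complemented:
            action = "complemented"
        else:
            action = "identity"
        report.append(ConversionAction(snp.name, action))
        keep.append(j)
        top = variant.illumina_top
        new_snps.append(replace(snp, allele1=top.first, allele2=top.second))
        columns.append(np.vectorize(mapping.__getitem__, otypes=["U2"])(column)
                       if len(column) else column)

    calls = (np.column_stack(columns) if columns
             else np.empty((dataset.n_samples, 0), dtype="U2"))
    converted = GenotypeDataset(
        samples=list(dataset.samples), snps=new_snps, calls=calls,
        coding=Coding.ILLUMINA_TOP, assembly=dataset.assembly,
        chip_name=dataset.chip_name, source=dataset.source,
        sample_origins=(list(dataset.sample_origins)
                        if dataset.sample_origins else None))
    return converted, report


def remap_positions(dataset: GenotypeDataset, target_assembly: str,
                    registry: Registry) -> GenotypeDataset:
    """Rewrite SNP coordinates for another assembly; genotypes unchanged.

    Requires TOP coding (assembly-invariant); forward-coded data must be
    converted first.  Variants without a mapping on the target assembly
    get the unmapped convention (chromosome "0", position 0).
    """
    if dataset.coding is not Coding.ILLUMINA_TOP:
        raise SnpHarmonyError(
            "remap_positions requires Illumina TOP coding; convert first "
            f"(dataset coding: {dataset.coding})")
    new_snps = []
    for snp in dataset.snps:
        variant = registry.resolve(snp.name, dataset.chip_name)
        loc = variant.location(target_assembly) if variant else None
        if loc is None or not loc.is_mapped:
            if variant is None:
                logger.warning("remap: SNP %s not in registry; unmapped",
                               snp.name)
            new_snps.append(replace(snp, chromosome=UNMAPPED_CHROM,
                                    position=UNMAPPED_POS))
        else:
            new_snps.append(replace(snp, chromosome=loc.chromosome,
                                    position=loc.position))
    out = dataset.copy()
    out.snps = new_snps
    out.assembly = target_assembly
    return out


def write_conversion_report(report: list[ConversionAction], path) -> None:
    from pathlib import Path

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write("snp\taction\n")
        for row in report:
            fh.write(f"{row.snp}\t{row.action}\n")
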