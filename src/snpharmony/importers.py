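"""Build registry variants from vendor manifest/annotation files.

TOP alleles are derived from the probe sequence via the TOP/BOT walk;
probes whose strand cannot be determined are still imported but flagged
``undetermined_strand`` — such variants are unusable for forward-coded
conversion of ambiguous SNPs, matching the FAO exclusion rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .errors import UndeterminedStrandError
from .io.affymetrix import AffymetrixRecord, read_affymetrix_annotation
from .io.illumina import ManifestRecord, read_illumina_manifest
from .registry import Location, Registry, Variant
from .strand import (
    AllelePair,
    Strand,
    StrandRelation,
    designate_strand,
    is_ambiguous,
    top_alleles,
)

logger = logging.getLogger(__name__)


@dataclass
class ImportReport:
    chip_name: str
    n_records: int = 0
    n_imported: int = 0
    n_flagged: int = 0
    n_skipped: int = 0


def _forward_from_relation(top: AllelePair,
                           relation: StrandRelation) -> AllelePair | None:
    if relation is StrandRelation.SAME:
        return top
    if relation is StrandRelation.OPPOSITE:
        return top.complemented()
    return None


def import_illumina_manifest(registry: Registry, path, chip_name: str,
                             assembly: str) -> ImportReport:
    """Import an Illumina CSV manifest for one chip on one assembly."""
    records = read_illumina_manifest(path)
    report = ImportReport(chip_name=chip_name, n_records=len(records))
    for rec in records:
        variant = _variant_from_illumina(rec, chip_name, assembly)
        if variant is None:
            report.n_skipped += 1
            continue
        registry.add_variant(variant)
        report.n_imported += 1
        if "undetermined_strand" in variant.flags:
            report.n_flagged += 1
    registry.chips.add(chip_name)
    return report


def _variant_from_illumina(rec: ManifestRecord, chip_name: str,
                           assembly: str) -> Variant | None:
    probe = rec.probe or rec.snp_string
    flags: set[str] = set()
    try:
        top = top_alleles(probe)
    except UndeterminedStrandError:
        try:
            top = AllelePair.from_string(rec.snp_string)
        except ValueError:
            logger.warning("skipping %s: unusable SNP string %r",
                           rec.name, rec.snp_string)
            return None
        flags.add("undetermined_strand")
    except ValueError:
        logger.warning("skipping %s: unparsable probe", rec.name)
        return None

    if "undetermined_strand" in flags:
        relation = StrandRelation.UNKNOWN
    elif rec.ref_strand == "+":
        relation = StrandRelation.SAME
    elif rec.ref_strand == "-":
        relation = StrandRelation.OPPOSITE
    else:
        relation = StrandRelation.UNKNOWN

    mapped = rec.chromosome != "0" and rec.position > 0
    location = Location(
        assembly=assembly,
        chromosome=rec.chromosome if mapped else "0",
        position=rec.position if mapped else 0,
        illumina_forward=_forward_from_relation(top, relation),
        strand_relation=relation,
        source="illumina")
    return Variant(
        name=rec.name, illumina_top=top, chip_names={chip_name},
        aliases={chip_name: rec.name}, probe_seq=probe,
        locations=[location], flags=flags, extra=dict(rec.extra))


def import_affymetrix_annotation(registry: Registry, path, chip_name: str,
                                 assembly: str) -> ImportReport:
    """Import an Affymetrix annotation table for one chip on one assembly.

    The flank sequence is taken to be written on the assembly forward
    strand, so its TOP/BOT designation fixes the strand relation; without
    a flank, the relation is recovered from the A/B alleles for
    unambiguous SNPs and left unknown (flagged) for ambiguous ones.
    Mapped positions are stored as Affymetrix-sourced locations, which may
    legitimately diverge from Illumina-sourced ones on the same assembly.
    """
    records = read_affymetrix_annotation(path)
    report = ImportReport(chip_name=chip_name, n_records=len(records))
    for rec in records:
        variant = _variant_from_affymetrix(rec, chip_name, assembly)
        if variant is None:
            report.n_skipped += 1
            continue
        registry.add_variant(variant)
        report.n_imported += 1
        if "undetermined_strand" in variant.flags:
            report.n_flagged += 1
    registry.chips.add(chip_name)
    return report


def _variant_from_affymetrix(rec: AffymetrixRecord, chip_name: str,
                             assembly: str) -> Variant | None:
    try:
        forward = AllelePair(rec.allele_a, rec.allele_b)
    except ValueError:
        logger.warning("skipping %s: bad alleles %s/%s", rec.probeset_id,
                       rec.allele_a, rec.allele_b)
        return None
    flags: set[str] = set()
    relation = StrandRelation.UNKNOWN
    top: AllelePair | None = None
    if rec.flank:
        try:
            strand = designate_strand(rec.flank)
        except ValueError:
            strand = Strand.UNDETERMINED
        if strand is not Strand.UNDETERMINED:
            top = top_alleles(rec.flank)
            relation = (StrandRelation.SAME if strand is Strand.TOP
                        else StrandRelation.OPPOSITE)
    if top is None:
        if is_ambiguous(forward):
            top = forward
            flags.add("undetermined_strand")
        else:
            # unambiguous: allele content fixes TOP and hence the relation
            if "A" in forward.as_set:
                top, relation = forward, StrandRelation.SAME
            else:
                pair = forward.complemented()
                first, second = sorted(pair.as_set)
                top = AllelePair(first, second)
                relation = StrandRelation.OPPOSITE

    expected = _forward_from_relation(top, relation)
    if expected is not None and expected.as_set != forward.as_set:
        logger.warning("%s: flank-derived strand contradicts alleles %s; "
                       "flagging", rec.name, forward)
        flags.add("strand_conflict")
        relation = StrandRelation.UNKNOWN

    mapped = rec.chromosome != "0" and rec.position > 0
    location = Location(
        assembly=assembly,
        chromosome=rec.chromosome if mapped else "0",
        position=rec.position if mapped else 0,
        illumina_forward=forward,
        strand_relation=relation,
        source="affymetrix")
    return Variant(
        name=rec.name, illumina_top=top, rs_id=rec.rs_id,
        chip_names={chip_name},
        aliases={chip_name: rec.probeset_id},
        probesets=[(chip_name, rec.probeset_id)],
        probe_seq=rec.flank, locations=[location], flags=flags,
        extra=dict(rec.extra))
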