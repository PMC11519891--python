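"""Illumina Final Report and CSV manifest parsing.

A Final Report is a long-format table (one row per sample x SNP) under a
``[Data]`` section, with genotype columns in one or more of the Top,
Forward or AB conventions.  A manifest is the vendor's per-SNP annotation
file: CSV with an ``[Assay]`` section carrying names, SNP strings, probe
source sequences and mapped positions.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..dataset import MISSING_CELL, GenotypeDataset, SampleInfo, SnpInfo
from ..errors import FormatError
from ..strand import Coding

logger = logging.getLogger(__name__)

# allele-column pairs searched in order of preference
_ALLELE_COLUMNS = (
    (Coding.ILLUMINA_TOP, "Allele1 - Top", "Allele2 - Top"),
    (Coding.ILLUMINA_FORWARD, "Allele1 - Forward", "Allele2 - Forward"),
    (Coding.ILLUMINA_AB, "Allele1 - AB", "Allele2 - AB"),
)


def read_illumina_report(path, prefer: Coding | None = None,
                         assembly: str | None = None) -> GenotypeDataset:
    """Read a Final Report; coding is taken from the allele columns found
    (Top preferred, then Forward, then AB, unless ``prefer`` pins one).

    "-" denotes a missing allele.  Every sample must report the same SNPs.
    """
    path = Path(path)
    header_meta, rows = _split_report(path)
    if not rows:
        raise FormatError(f"{path}: empty [Data] section")
    columns = rows[0]
    required = ("SNP Name", "Sample ID")
    for col in required:
        if col not in columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")

    candidates = [(c, a1, a2) for c, a1, a2 in _ALLELE_COLUMNS
                  if a1 in columns and a2 in columns]
    if prefer is not None:
        candidates = [c for c in candidates if c[0] is prefer]
    if not candidates:
        raise FormatError(
            f"{path}: no supported allele column pair (Top/Forward/AB)"
            + (f" for coding {prefer.value}" if prefer else ""))
    coding, col_a1, col_a2 = candidates[0]

    idx = {name: i for i, name in enumerate(columns)}
    per_sample: dict[str, list[tuple[str, str]]] = {}
    order: list[str] = []
    for fields in rows[1:]:
        snp = fields[idx["SNP Name"]]
        sample = fields[idx["Sample ID"]]
        a1, a2 = fields[idx[col_a1]], fields[idx[col_a2]]
        if sample not in per_sample:
            per_sample[sample] = []
        per_sample[sample].append((snp, _symbol(a1) + _symbol(a2)))
        if len(per_sample) == 1:
            order.append(snp)

    n_snps = len(order)
    samples, matrix = [], []
    snp_pos = {name: j for j, name in enumerate(order)}
    for sample_id, entries in per_sample.items():
        if len(entries) != n_snps:
            raise FormatError(
                f"{path}: sample {sample_id!r} reports {len(entries)} SNPs, "
                f"expected {n_snps}")
        row = [MISSING_CELL] * n_snps
        for snp, cell in entries:
            j = snp_pos.get(snp)
            if j is None:
                raise FormatError(
                    f"{path}: sample {sample_id!r} reports unknown SNP {snp!r}")
            row[j] = cell if "0" not in cell else MISSING_CELL
        samples.append(SampleInfo(fid=sample_id, iid=sample_id))
        matrix.append(row)

    snps = [SnpInfo(name=name) for name in order]
    return GenotypeDataset(
        samples=samples, snps=snps, calls=np.array(matrix, dtype="U2"),
        coding=coding, assembly=assembly,
        chip_name=header_meta.get("Content"))


def write_illumina_report(dataset: GenotypeDataset, path) -> Path:
    """Write a minimal Final Report (used by the synthetic-data generator
    and for format conversion round trips)."""
    if dataset.coding is None:
        raise ValueError("dataset coding must be known to write a report")
    suffix = {Coding.ILLUMINA_TOP: "Top", Coding.ILLUMINA_FORWARD: "Forward",
              Coding.ILLUMINA_AB: "AB"}.get(dataset.coding)
    if suffix is None:
        raise ValueError(f"unsupported report coding: {dataset.coding}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write("[Header]\n")
        fh.write("GSGT Version\tsnpharmony\n")
        if dataset.chip_name:
            fh.write(f"Content\t{dataset.chip_name}\n")
        fh.write(f"Num SNPs\t{dataset.n_snps}\n")
        fh.write(f"Num Samples\t{dataset.n_samples}\n")
        fh.write("[Data]\n")
        fh.write(f"SNP Name\tSample ID\tAllele1 - {suffix}\t"
                 f"Allele2 - {suffix}\n")
        for i, sample in enumerate(dataset.samples):
            for j, snp in enumerate(dataset.snps):
                cell = dataset.calls[i, j]
                a1 = "-" if cell[0] == "0" else cell[0]
                a2 = "-" if cell[1] == "0" else cell[1]
                fh.write(f"{snp.name}\t{sample.iid}\t{a1}\t{a2}\n")
    return path


def _symbol(a: str) -> str:
    return "0" if a in ("-", "", "0") else a


def _split_report(path: Path):
    """Return ({header key: value}, [data rows as field lists])."""
    meta: dict[str, str] = {}
    rows: list[list[str]] = []
    section = None
    for line in path.read_text().splitlines():
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("[") and stripped.endswith("]"):
            section = stripped[1:-1].lower()
            continue
        if section == "header":
            parts = line.split("\t")
            if len(parts) >= 2:
                meta[parts[0].strip()] = parts[1].strip()
        elif section == "data":
            rows.append(line.split("\t"))
    if section is None:
        raise FormatError(f"{path}: no [Header]/[Data] sections found")
    return meta, rows


@dataclass(frozen=True)
class ManifestRecord:
    """One ``[Assay]`` row of an Illumina manifest, normalized."""

    name: str
    snp_string: str  # e.g. "[A/G]"
    probe: str | None  # source sequence with the [X/Y] site, uppercased
    chromosome: str = "0"
    position: int = 0
    ref_strand: str | None = None  # '+'/'-': TOP relative to assembly forward
    extra: dict = field(default_factory=dict)


def read_illumina_manifest(path) -> list[ManifestRecord]:
    """Parse the ``[Assay]`` section of an Illumina CSV manifest.

    Rows without a SNP string are skipped with a logged reason; rows
    without a source sequence fall back to the bare SNP string (whose
    strand is then decidable only for unambiguous SNPs).
    """
    path = Path(path)
    records: list[ManifestRecord] = []
    in_assay, header = False, None
    with path.open(newline="") as fh:
        for fields in csv.reader(fh):
            if not fields:
                continue
            tag = fields[0].strip()
            if tag.startswith("[") and tag.endswith("]"):
                in_assay = tag.lower() == "[assay]"
                header = None
                continue
            if not in_assay:
                continue
            if header is None:
                header = {name.strip(): i for i, name in enumerate(fields)}
                continue
            row = {name: (fields[i].strip() if i < len(fields) else "")
                   for name, i in header.items()}
            name = row.get("Name") or row.get("IlmnID")
            snp = row.get("SNP", "")
            if not name:
                logger.warning("%s: skipping assay row without Name", path)
                continue
            if not snp:
                logger.warning("%s: skipping %s — no SNP string", path, name)
                continue
            probe = (row.get("SourceSeq") or row.get("TopGenomicSeq") or "")
            probe = probe.upper() or None
            pos = row.get("MapInfo", "")
            known = {"Name", "IlmnID", "SNP", "SourceSeq", "TopGenomicSeq",
                     "Chr", "MapInfo", "RefStrand"}
            records.append(ManifestRecord(
                name=name, snp_string=snp.upper(), probe=probe,
                chromosome=row.get("Chr") or "0",
                position=int(pos) if pos.isdigit() else 0,
                ref_strand=row.get("RefStrand") or None,
                extra={k: v for k, v in row.items()
                       if k not in known and v}))
    if header is None and not records:
        raise FormatError(f"{path}: no [Assay] section found")
    return records
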