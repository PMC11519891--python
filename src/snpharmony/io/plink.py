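"""PLINK text (PED/MAP) and binary (BED/BIM/FAM) readers and writers.

The binary writer is bit-exact against the published BED layout: magic
bytes 0x6C 0x1B, mode byte 0x01 (SNP-major), then one block per SNP of
2-bit calls packed four samples per byte, low bits first, padded to a
whole byte.  Codes: 00 = homozygous allele1, 01 = missing, 10 =
heterozygous, 11 = homozygous allele2.  Writing is deterministic: the same
dataset always yields byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from ..dataset import MISSING_CELL, GenotypeDataset, SampleInfo, SnpInfo
from ..errors import FormatError
from ..strand import Coding

BED_MAGIC = bytes([0x6C, 0x1B])
BED_SNP_MAJOR = 0x01

_HOM1, _MISS, _HET, _HOM2 = 0, 1, 2, 3


def read_plink_text(ped_path, map_path, coding: Coding | None = None,
                    assembly: str | None = None,
                    chip_name: str | None = None) -> GenotypeDataset:
    """Read whitespace-delimited PED/MAP into a dataset.

    PED columns 1-6 (FID, IID, father, mother, sex, phenotype) are kept as
    sample metadata; allele symbol "0" means missing.  The MAP may have 3
    or 4 columns (centimorgans optional).  PED carries no coding
    information, so ``coding`` stays ``None`` unless supplied.
    """
    snps = []
    for lineno, line in enumerate(_lines(map_path), 1):
        fields = line.split()
        if len(fields) == 4:
            chrom, name, _cm, pos = fields
        elif len(fields) == 3:
            chrom, name, pos = fields
        else:
            raise FormatError(f"{map_path}:{lineno}: expected 3 or 4 columns")
        snps.append(SnpInfo(name=name, chromosome=chrom, position=int(pos)))

    samples, rows = [], []
    for lineno, line in enumerate(_lines(ped_path), 1):
        fields = line.split()
        alleles = fields[6:]
        if len(fields) < 6 or len(alleles) % 2:
            raise FormatError(
                f"{ped_path}:{lineno}: odd allele count ({len(alleles)})")
        if len(alleles) != 2 * len(snps):
            raise FormatError(
                f"{ped_path}:{lineno}: {len(alleles) // 2} genotypes but MAP "
                f"lists {len(snps)} SNPs")
        samples.append(SampleInfo(*fields[:6]))
        rows.append([_cell(alleles[2 * j], alleles[2 * j + 1])
                     for j in range(len(snps))])

    calls = (np.array(rows, dtype="U2") if rows
             else np.empty((0, len(snps)), dtype="U2"))
    return GenotypeDataset(samples=samples, snps=snps, calls=calls,
                           coding=coding, assembly=assembly,
                           chip_name=chip_name)


def write_plink_text(dataset: GenotypeDataset, prefix) -> tuple[Path, Path]:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    with map_path.open("w") as fh:
        for s in dataset.snps:
            fh.write(f"{s.chromosome}\t{s.name}\t0\t{s.position}\n")
    with ped_path.open("w") as fh:
        for i, sample in enumerate(dataset.samples):
            cells = " ".join(f"{c[0]} {c[1]}" for c in dataset.calls[i])
            head = "\t".join([sample.fid, sample.iid, sample.father,
                              sample.mother, sample.sex, sample.phenotype])
            fh.write(head + ("\t" + cells if cells else "") + "\n")
    return ped_path, map_path


def _resolve_alleles(dataset: GenotypeDataset, j: int) -> tuple[str, str]:
    """Allele1/allele2 for SNP ``j``: the declared pair, completed from the
    observed calls when the sidecar says "0"."""
    snp = dataset.snps[j]
    a1, a2 = snp.allele1, snp.allele2
    observed = []
    for cell in dataset.calls[:, j]:
        for symbol in cell:
            if symbol != "0" and symbol not in observed:
                observed.append(symbol)
    for symbol in observed:
        if symbol in (a1, a2):
            continue
        if a1 == "0":
            a1 = symbol
        elif a2 == "0":
            a2 = symbol
        else:
            raise FormatError(
                f"{snp.name}: allele {symbol!r} outside declared pair "
                f"{a1}/{a2}; not biallelic")
    return a1, a2


def write_plink_binary(dataset: GenotypeDataset, prefix) -> tuple[Path, Path, Path]:
    """Write BED+BIM+FAM.  BIM columns: chrom, name, cM (0), bp, allele1,
    allele2 — allele1 is the first declared allele (the first TOP allele
    for converted datasets)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    bed_path, bim_path, fam_path = (prefix.with_suffix(ext)
                                    for ext in (".bed", ".bim", ".fam"))
    n = dataset.n_samples
    block = (n + 3) // 4

    with fam_path.open("w") as fh:
        for s in dataset.samples:
            fh.write(f"{s.fid}\t{s.iid}\t{s.father}\t{s.mother}\t{s.sex}\t"
                     f"{s.phenotype}\n")

    with bim_path.open("w") as bim, bed_path.open("wb") as bed:
        bed.write(BED_MAGIC + bytes([BED_SNP_MAJOR]))
        for j, snp in enumerate(dataset.snps):
            a1, a2 = _resolve_alleles(dataset, j)
            bim.write(f"{snp.chromosome}\t{snp.name}\t0\t{snp.position}\t"
                      f"{a1}\t{a2}\n")
            buf = bytearray(block)
            for i in range(n):
                cell = dataset.calls[i, j]
                if cell == MISSING_CELL:
                    code = _MISS
                else:
                    pair = {cell[0], cell[1]}
                    if pair == {a1}:
                        code = _HOM1
                    elif pair == {a2}:
                        code = _HOM2
                    elif pair == {a1, a2}:
                        code = _HET
                    else:
                        raise FormatError(
                            f"{snp.name}: call {cell!r} not expressible with "
                            f"alleles {a1}/{a2}")
                buf[i // 4] |= code << (2 * (i % 4))
            bed.write(bytes(buf))
    return bed_path, bim_path, fam_path


def read_plink_binary(prefix, coding: Coding | None = None,
                      assembly: str | None = None,
                      chip_name: str | None = None) -> GenotypeDataset:
    prefix = Path(prefix)
    bed_path, bim_path, fam_path = (prefix.with_suffix(ext)
                                    for ext in (".bed", ".bim", ".fam"))
    snps = []
    for lineno, line in enumerate(_lines(bim_path), 1):
        fields = line.split()
        if len(fields) != 6:
            raise FormatError(f"{bim_path}:{lineno}: expected 6 columns")
        chrom, name, _cm, pos, a1, a2 = fields
        snps.append(SnpInfo(name=name, chromosome=chrom, position=int(pos),
                            allele1=a1, allele2=a2))
    samples = []
    for lineno, line in enumerate(_lines(fam_path), 1):
        fields = line.split()
        if len(fields) != 6:
            raise FormatError(f"{fam_path}:{lineno}: expected 6 columns")
        samples.append(SampleInfo(*fields))

    data = bed_path.read_bytes()
    if data[:2] != BED_MAGIC:
        raise FormatError(f"{bed_path}: bad magic bytes {data[:2].hex()}")
    if data[2] != BED_SNP_MAJOR:
        raise FormatError(f"{bed_path}: only SNP-major (mode 0x01) supported")
    n = len(samples)
    block = (n + 3) // 4
    body = data[3:]
    if len(body) != block * len(snps):
        raise FormatError(
            f"{bed_path}: truncated — {len(body)} data bytes, expected "
            f"{block * len(snps)}")

    calls = np.full((n, len(snps)), MISSING_CELL, dtype="U2")
    for j, snp in enumerate(snps):
        decode = {_HOM1: snp.allele1 * 2, _MISS: MISSING_CELL,
                  _HET: snp.allele1 + snp.allele2, _HOM2: snp.allele2 * 2}
        chunk = body[j * block:(j + 1) * block]
        for i in range(n):
            code = (chunk[i // 4] >> (2 * (i % 4))) & 0b11
            calls[i, j] = decode[code]
    return GenotypeDataset(samples=samples, snps=snps, calls=calls,
                           coding=coding, assembly=assembly,
                           chip_name=chip_name)


def _cell(a: str, b: str) -> str:
    if a == "0" or b == "0":
        return MISSING_CELL
    return a + b


def _lines(path):
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.strip():
                yield line
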