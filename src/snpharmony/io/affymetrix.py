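"""Affymetrix annotation tables and tabular genotype calls.

Annotation files are CSV with ``#``-commented header lines.  Intensity
(CEL) files are out of scope; the supported genotype input is a calls
table (probeset x sample) holding either A/B dosage codes (0/1/2, -1
missing) or nucleotide pairs on the assembly forward strand ("CG", "--"
missing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ..dataset import MISSING_CELL, GenotypeDataset, SampleInfo, SnpInfo
from ..errors import FormatError
from ..strand import Coding

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AffymetrixRecord:
    probeset_id: str
    name: str  # customer SNP id when present, else the Affy SNP id
    allele_a: str
    allele_b: str
    chromosome: str = "0"
    position: int = 0
    flank: str | None = None  # sequence with [X/Y] site, uppercased
    rs_id: str | None = None
    extra: dict = field(default_factory=dict)


_COLUMNS = {
    "probeset_id": ("Probe Set ID", "probeset_id"),
    "affy_id": ("Affy SNP ID", "affy_snp_id"),
    "cust_id": ("cust_snpid", "cust_id"),
    "rs_id": ("dbSNP RS ID", "rs_id"),
    "chrom": ("Chromosome", "chromosome"),
    "pos": ("Physical Position", "position"),
    "flank": ("Flank", "flank"),
    "allele_a": ("Allele A", "allele_a"),
    "allele_b": ("Allele B", "allele_b"),
}


def read_affymetrix_annotation(path) -> list[AffymetrixRecord]:
    """Parse a header-commented Affymetrix annotation CSV.  Rows lacking a
    flank sequence and alleles are skipped with a logged reason."""
    path = Path(path)
    try:
        table = pd.read_csv(path, comment="#", dtype=str).fillna("")
    except Exception as exc:  # noqa: BLE001 — normalize parser errors
        raise FormatError(f"{path}: cannot parse annotation CSV: {exc}") from exc

    def col(key: str) -> str | None:
        for candidate in _COLUMNS[key]:
            if candidate in table.columns:
                return candidate
        return None

    required = ["probeset_id", "allele_a", "allele_b"]
    missing = [k for k in required if col(k) is None]
    if missing:
        raise FormatError(f"{path}: missing columns for {missing}")

    records = []
    for _, row in table.iterrows():
        def get(key: str, default: str = "") -> str:
            c = col(key)
            return str(row[c]).strip() if c else default

        probeset = get("probeset_id")
        flank = get("flank").upper() or None
        allele_a, allele_b = get("allele_a").upper(), get("allele_b").upper()
        if not allele_a or not allele_b:
            logger.warning("%s: skipping %s — no alleles", path, probeset)
            continue
        if flank is None:
            logger.warning("%s: %s has no flank; strand undetermined",
                           path, probeset)
        pos = get("pos")
        rs = get("rs_id")
        records.append(AffymetrixRecord(
            probeset_id=probeset,
            name=get("cust_id") or get("affy_id") or probeset,
            allele_a=allele_a, allele_b=allele_b,
            chromosome=get("chrom") or "0",
            position=int(pos) if pos.isdigit() else 0,
            flank=flank,
            rs_id=rs if rs and rs != "---" else None))
    return records


def read_affymetrix_calls(path, chip_name: str | None = None,
                          assembly: str | None = None) -> GenotypeDataset:
    """Read a probeset x sample calls TSV.

    Dosage codes (0/1/2 of the B allele, -1 missing) yield an A/B-coded
    dataset; nucleotide pairs yield ``affymetrix_forward`` coding.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if table.shape[1] < 2:
        raise FormatError(f"{path}: need a probeset column plus samples")
    snp_col = table.columns[0]
    sample_ids = list(table.columns[1:])
    values = table[sample_ids].to_numpy(dtype=str)

    flat = {v for v in values.ravel()}
    if flat <= {"-1", "0", "1", "2", ""}:
        coding = Coding.ILLUMINA_AB
        decode = {"0": "AA", "1": "AB", "2": "BB", "-1": MISSING_CELL,
                  "": MISSING_CELL}
        cells = np.vectorize(decode.__getitem__)(values)
    else:
        coding = Coding.AFFYMETRIX_FORWARD
        def decode_pair(v: str) -> str:
            v = v.strip().upper().replace("/", "")
            if v in ("--", "", "NOCALL", "00"):
                return MISSING_CELL
            if len(v) != 2 or not set(v) <= set("ACGT"):
                raise FormatError(f"{path}: bad genotype value {v!r}")
            return v
        cells = np.vectorize(decode_pair)(values)

    snps = [SnpInfo(name=name) for name in table[snp_col]]
    samples = [SampleInfo(fid=s, iid=s) for s in sample_ids]
    return GenotypeDataset(samples=samples, snps=snps, calls=cells.T,
                           coding=coding, assembly=assembly,
                           chip_name=chip_name)
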