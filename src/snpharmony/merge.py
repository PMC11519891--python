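"""Unified-genotype construction: stable sample IDs, SNP-union merge, and
identity-by-state (IBS) duplicate detection.

The merge takes any number of TOP-coded datasets on one assembly, unifies
SNP names to registry canonical names via chip aliases, and produces one
samples x union-of-SNPs matrix, ordered by genome position (unmapped SNPs
last, by name).  Samples genotyped on a chip lacking some union SNP are
missing there — no imputation, no missingness or MAF filtering; the only
downstream filter offered is IBS duplicate removal.

Pairwise IBS between two samples is the mean, over loci where both calls
are non-missing, of the per-locus fraction of shared alleles counting
multiplicity (0, 0.5 or 1).  Values near 1 indicate the same animal
genotyped twice, which happens when overlapping published datasets are
both integrated.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dataset import MISSING_CELL, GenotypeDataset, SampleInfo, SnpInfo
from .errors import MergeConflictError, SnpHarmonyError
from .registry import Registry
from .strand import Coding

SPECIES_CODES = {"sheep": "OA", "goat": "CH"}
_ID_RE = re.compile(r"^[A-Z]{2}[A-Z]{2}-[A-Z0-9]{3}-[0-9]{9}$")


@dataclass(frozen=True)
class SmarterId:
    """Stable sample ID: country (ISO alpha-2) + species code (OA sheep,
    CH goat) + 3-character breed code + 9-digit counter, e.g.
    ``UYOA-CRR-000003890``."""

    country: str
    species: str  # 2-letter species code
    breed_code: str
    counter: int

    def __post_init__(self) -> None:
        if self.counter <= 0:
            raise ValueError("counter must be positive")
        if not _ID_RE.match(str(self)):
            raise ValueError(f"malformed SMARTER ID: {self}")

    def __str__(self) -> str:
        return f"{self.country}{self.species}-{self.breed_code}-{self.counter:09d}"

    @classmethod
    def parse(cls, text: str) -> "SmarterId":
        if not _ID_RE.match(text):
            raise ValueError(f"malformed SMARTER ID: {text!r}")
        return cls(country=text[:2], species=text[2:4], breed_code=text[5:8],
                   counter=int(text[9:]))


@dataclass
class IdState:
    """Persistent ID-assignment state: one counter per species scope plus
    the (dataset, original ID) -> assigned ID memory that makes
    re-imports idempotent."""

    counter: int = 0
    assigned: dict = field(default_factory=dict)  # "dataset\x1forig" -> id str

    @staticmethod
    def _key(dataset: str, original_id: str) -> str:
        return f"{dataset}\x1f{original_id}"

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"counter": self.counter, "assigned": self.assigned},
            sort_keys=True, indent=0) + "\n")

    @classmethod
    def load(cls, path) -> "IdState":
        doc = json.loads(Path(path).read_text())
        return cls(counter=int(doc["counter"]), assigned=dict(doc["assigned"]))


def assign_smarter_ids(samples, species: str, state: IdState | None = None,
                       ) -> tuple[list[SmarterId], IdState]:
    """Assign stable IDs to sample metadata rows.

    ``samples`` is an iterable of mappings with at least ``country``
    (alpha-2), ``breed_code`` (3 chars), ``original_id`` and ``dataset``.
    Previously seen (dataset, original ID) pairs keep their existing ID
    and do not advance the counter; replaying the same input yields
    identical output.  The counter scope is one per species.
    """
    state = state or IdState()
    species_code = SPECIES_CODES.get(species, species).upper()
    if len(species_code) != 2:
        raise ValueError(f"cannot derive 2-letter species code from {species!r}")

    problems = []
    for row in samples:
        if not row.get("country") or not row.get("breed_code"):
            problems.append(row.get("original_id", "<unknown>"))
    if problems:
        raise SnpHarmonyError(
            "samples missing country/breed code: " + ", ".join(map(str, problems)))

    ids: list[SmarterId] = []
    for row in samples:
        key = IdState._key(row.get("dataset", ""), row["original_id"])
        existing = state.assigned.get(key)
        if existing is not None:
            ids.append(SmarterId.parse(existing))
            continue
        state.counter += 1
        sid = SmarterId(country=row["country"].upper(), species=species_code,
                        breed_code=row["breed_code"].upper(),
                        counter=state.counter)
        state.assigned[key] = str(sid)
        ids.append(sid)
    return ids, state


def _chromosome_rank(chrom: str):
    return (0, int(chrom), "") if chrom.isdigit() else (1, 0, chrom)


def merge_datasets(datasets: list[GenotypeDataset], registry: Registry,
                   on_unknown: str = "error") -> GenotypeDataset:
    """Merge TOP-coded datasets on one assembly into a SNP-union matrix.

    Source calls are copied verbatim into their (sample, canonical SNP)
    cells; every cell a sample's chip does not cover is missing.  The
    same canonical SNP appearing with conflicting TOP alleles across
    inputs is a hard error.
    """
    if not datasets:
        raise ValueError("nothing to merge")
    for ds in datasets:
        if ds.coding is not Coding.ILLUMINA_TOP:
            raise SnpHarmonyError(
                f"dataset {ds.source or ds.chip_name}: merge requires "
                f"Illumina TOP coding, got {ds.coding}")
    assemblies = {ds.assembly for ds in datasets}
    if len(assemblies) > 1:
        raise SnpHarmonyError(f"datasets span assemblies {sorted(map(str, assemblies))}; "
                              "remap to one assembly first")

    # canonicalize and collect the union
    union: dict[str, SnpInfo] = {}
    resolved: list[list[str | None]] = []
    for ds in datasets:
        names: list[str | None] = []
        for snp in ds.snps:
            variant = registry.resolve(snp.name, ds.chip_name)
            if variant is None:
                if on_unknown == "drop":
                    names.append(None)
                    continue
                raise SnpHarmonyError(
                    f"SNP {snp.name} (dataset {ds.source or ds.chip_name}) "
                    "not found in registry")
            top = variant.illumina_top
            known = {snp.allele1, snp.allele2} - {"0"}
            if known and not known <= top.as_set:
                raise MergeConflictError(
                    f"{variant.name}: dataset alleles {sorted(known)} conflict "
                    f"with registry TOP {top}")
            names.append(variant.name)
            prior = union.get(variant.name)
            info = SnpInfo(name=variant.name, chromosome=snp.chromosome,
                           position=snp.position, allele1=top.first,
                           allele2=top.second)
            if prior is None:
                union[variant.name] = info
            elif (prior.allele1, prior.allele2) != (info.allele1, info.allele2):
                raise MergeConflictError(
                    f"{variant.name}: conflicting TOP alleles across inputs")
        resolved.append(names)

    ordered = sorted(
        union.values(),
        key=lambda s: ((1, (1, 0, ""), 0, s.name) if s.chromosome == "0"
                       else (0, _chromosome_rank(s.chromosome), s.position,
                             s.name)))
    col_of = {s.name: j for j, s in enumerate(ordered)}

    n_samples = sum(ds.n_samples for ds in datasets)
    calls = np.full((n_samples, len(ordered)), MISSING_CELL, dtype="U2")
    samples: list[SampleInfo] = []
    origins: list[str] = []
    row = 0
    for k, ds in enumerate(datasets):
        cols = [col_of[name] if name is not None else -1
                for name in resolved[k]]
        keep = [j for j, c in enumerate(cols) if c >= 0]
        target = [cols[j] for j in keep]
        calls[row:row + ds.n_samples, target] = ds.calls[:, keep]
        samples.extend(ds.samples)
        origins.extend([ds.source or ds.chip_name or f"dataset{k}"] * ds.n_samples)
        row += ds.n_samples

    return GenotypeDataset(
        samples=samples, snps=ordered, calls=calls,
        coding=Coding.ILLUMINA_TOP, assembly=datasets[0].assembly,
        chip_name="merged", source="merged", sample_origins=origins)


# -- identity by state ----------------------------------------------------

def _dosages(dataset: GenotypeDataset) -> np.ndarray:
    """allele2 dosage per cell (0/1/2), -1 for missing."""
    from .io.plink import _resolve_alleles

    out = np.full(dataset.calls.shape, -1, dtype=np.int8)
    for j, snp in enumerate(dataset.snps):
        a1, a2 = _resolve_alleles(dataset, j)
        col = dataset.calls[:, j]
        for cell in np.unique(col):
            if cell == MISSING_CELL:
                continue
            symbols = (cell[0], cell[1])
            if not set(symbols) <= {a1, a2}:
                raise SnpHarmonyError(
                    f"{snp.name}: call {cell!r} outside alleles {a1}/{a2}")
            out[col == cell, j] = symbols.count(a2)
    return out


def compute_ibs(calls_a, calls_b) -> float | None:
    """Mean IBS between two call vectors (dtype-U2 cells over the same
    SNPs with the same allele definitions); ``None`` when no locus is
    jointly non-missing."""
    a = np.asarray(calls_a, dtype="U2")
    b = np.asarray(calls_b, dtype="U2")
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    scores, n = [], 0
    for x, y in zip(a, b):
        if x == MISSING_CELL or y == MISSING_CELL:
            continue
        xa = sorted((x[0], x[1]))
        ya = sorted((y[0], y[1]))
        shared = sum(p == q for p, q in zip(xa, ya))
        scores.append(shared / 2)
        n += 1
    return (sum(scores) / n) if n else None


DEFAULT_IBS_THRESHOLD = 0.95


@dataclass(frozen=True)
class IbsPair:
    sample_a: tuple[str, str]
    sample_b: tuple[str, str]
    score: float
    n_loci: int


@dataclass(frozen=True)
class FlaggedPair:
    sample_a: tuple[str, str]
    sample_b: tuple[str, str]
    score: float
    n_loci: int
    survivor: tuple[str, str]
    removed: tuple[str, str]


@dataclass
class IbsReport:
    pairs: list[IbsPair]
    flagged: list[FlaggedPair]
    threshold: float

    @property
    def removal_list(self) -> list[tuple[str, str]]:
        seen, out = set(), []
        for fp in self.flagged:
            if fp.removed not in seen:
                seen.add(fp.removed)
                out.append(fp.removed)
        return out

    def write_tsv(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        flagged = {(fp.sample_a, fp.sample_b): fp for fp in self.flagged}
        with path.open("w") as fh:
            fh.write("sampleA\tsampleB\tibs\tn_loci\tflagged\tsurvivor\n")
            for p in self.pairs:
                fp = flagged.get((p.sample_a, p.sample_b))
                fh.write("\t".join([
                    "/".join(p.sample_a), "/".join(p.sample_b),
                    f"{p.score:.6f}", str(p.n_loci),
                    "yes" if fp else "no",
                    "/".join(fp.survivor) if fp else "-"]) + "\n")


def find_duplicates(dataset: GenotypeDataset,
                    threshold: float = DEFAULT_IBS_THRESHOLD,
                    mode: str = "all") -> IbsReport:
    """Flag sample pairs with IBS >= ``threshold``.

    ``mode="between"`` compares only samples originating from different
    source datasets (the overlap-between-background-datasets case);
    ``mode="all"`` (default) also compares within one dataset.  The
    survivor of a flagged pair is the sample with fewer missing calls;
    ties prefer the earlier dataset, then the earlier sample.
    """
    if mode not in ("all", "between"):
        raise ValueError("mode must be 'all' or 'between'")
    dosage = _dosages(dataset)
    present = dosage >= 0
    n = dataset.n_samples
    missing_count = (~present).sum(axis=1)
    origin_rank: dict[str, int] = {}
    for i in range(n):
        origin_rank.setdefault(dataset.origin_of(i), len(origin_rank))

    pairs: list[IbsPair] = []
    flagged: list[FlaggedPair] = []
    for i in range(n):
        for j in range(i + 1, n):
            if mode == "between" and \
                    dataset.origin_of(i) == dataset.origin_of(j):
                continue
            joint = present[i] & present[j]
            n_loci = int(joint.sum())
            if n_loci == 0:
                continue  # no comparison possible
            diff = np.abs(dosage[i, joint] - dosage[j, joint])
            score = float(1.0 - diff.mean() / 2.0)
            key_a, key_b = dataset.samples[i].key, dataset.samples[j].key
            pairs.append(IbsPair(key_a, key_b, score, n_loci))
            if score >= threshold:
                rank_i = (missing_count[i],
                          origin_rank[dataset.origin_of(i)], i)
                rank_j = (missing_count[j],
                          origin_rank[dataset.origin_of(j)], j)
                survivor, removed = ((key_a, key_b) if rank_i <= rank_j
                                     else (key_b, key_a))
                flagged.append(FlaggedPair(key_a, key_b, score, n_loci,
                                           survivor, removed))
    return IbsReport(pairs=pairs, flagged=flagged, threshold=threshold)


def drop_samples(dataset: GenotypeDataset,
                 keys: list[tuple[str, str]]) -> GenotypeDataset:
    """Return the dataset without the listed sample keys (dedup is
    reported, never applied silently — this is the explicit apply step)."""
    drop = set(keys)
    keep = [i for i, s in enumerate(dataset.samples) if s.key not in drop]
    out = dataset.copy()
    out.samples = [dataset.samples[i] for i in keep]
    out.calls = dataset.calls[keep]
    if dataset.sample_origins is not None:
        out.sample_origins = [dataset.sample_origins[i] for i in keep]
    return out
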