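"""Synthetic-data generator: registries, manifests, genotype datasets in
any coding, metadata tables and planted duplicate samples.

Everything is driven by one integer seed; independent substreams are
derived with fixed offsets so adding one more generated artifact never
shifts the others.  Genotypes are drawn per SNP from Hardy-Weinberg
equilibrium at a uniform random allele frequency and then re-expressed in
the requested coding with the exact inverse of the TOP conversion, so a
truth record allows end-to-end verification of inference, conversion,
merging and duplicate detection.

Two reference SNPs with well-known conversion behaviour are always
included: DU186191_327.1 (unambiguous, TOP A/G, forward strand opposite
to TOP on both Oar_v3.1 and Oar_v4.0) and OAR1_103790218.1 (ambiguous,
TOP C/G, opposite on Oar_v3.1 and same on Oar_v4.0).  The strand
relations are the ones their published conversion examples imply; the
probe flanks here are synthetic, constructed to reproduce the same
TOP/BOT designation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dataset import MISSING_CELL, GenotypeDataset, SampleInfo, SnpInfo
from .errors import UnresolvableStrandError
from .io.illumina import write_illumina_report
from .io.plink import write_plink_binary, write_plink_text
from .merge import SPECIES_CODES
from .registry import Location, Registry, Variant
from .strand import (
    AllelePair,
    Coding,
    GenotypeCall,
    Strand,
    StrandRelation,
    designate_strand,
    inverse_convert_genotype,
    reverse_complement,
    top_alleles,
)

_UNAMBIGUOUS = (("A", "G"), ("A", "C"))
_AMBIGUOUS = (("A", "T"), ("C", "G"))
_COUNTRIES = (("Uruguay", "UY"), ("Greece", "GR"), ("Italy", "IT"),
              ("Spain", "ES"), ("France", "FR"), ("Sweden", "SE"))
_BREEDS = (("Creole", "CRR"), ("Chios", "CHI"), ("Merino", "MER"),
           ("Texel", "TEX"), ("Frizarta", "FRZ"))
_PURPOSES = ("dairy", "meat", "wool", "mixed", None)


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic scenario.

    The defaults are the conditions the package is validated under:
    100 SNPs x 20 samples, 2% missing calls, 20% ambiguous (A/T-C/G)
    SNPs, half of the per-assembly mappings on the opposite strand, 80%
    GPS coverage, duplicates perturbed by setting 2% of their calls
    missing.
    """

    n_snps: int = 100
    n_samples: int = 20
    coding: Coding = Coding.ILLUMINA_TOP
    assemblies: tuple[str, ...] = ("Oar_v3.1", "Oar_v4.0")
    fraction_ambiguous: float = 0.2
    fraction_opposite: float = 0.5
    missing_rate: float = 0.02
    gps_probability: float = 0.8
    n_duplicates: int = 0
    duplicate_missing_rate: float = 0.02
    seed: int = 0
    chip_name: str = "SyntheticChip50K"
    species: str = "sheep"
    flank_length: int = 10
    n_affymetrix_snps: int = 0  # also annotate this many SNPs on an Affy chip

    def __post_init__(self) -> None:
        for name in ("fraction_ambiguous", "fraction_opposite",
                     "missing_rate", "gps_probability",
                     "duplicate_missing_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.n_snps < 2:
            raise ValueError("n_snps must be >= 2 (reference SNPs included)")

    @property
    def dataset_assembly(self) -> str:
        return self.assemblies[-1]

    @property
    def affymetrix_chip_name(self) -> str:
        return "SyntheticAffy60K"


@dataclass
class Truth:
    """Ground truth accompanying a generated dataset."""

    coding: Coding
    top_calls: np.ndarray
    duplicate_pairs: list[tuple[tuple[str, str], tuple[str, str]]]
    excluded_snps: list[str]
    allele1_freqs: np.ndarray


def _rng(spec: FixtureSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stream])


def _reference_variants(assemblies: tuple[str, ...]) -> list[Variant]:
    """The two always-included conversion reference SNPs (synthetic
    flanks, table-implied strand relations)."""
    out = []
    specs = [
        # name, top, probe, {assembly: relation}
        ("DU186191_327.1", ("A", "G"), "GCTTCCAGGA[A/G]TCCTGGCTTA",
         {"Oar_v3.1": StrandRelation.OPPOSITE,
          "Oar_v4.0": StrandRelation.OPPOSITE}),
        ("OAR1_103790218.1", ("C", "G"), "TGGCAAGTCA[C/G]CTCGGTAGGT",
         {"Oar_v3.1": StrandRelation.OPPOSITE,
          "Oar_v4.0": StrandRelation.SAME}),
    ]
    for k, (name, top, probe, relations) in enumerate(specs):
        pair = AllelePair(*top)
        assert top_alleles(probe) == pair
        locations = []
        for a, assembly in enumerate(assemblies):
            relation = relations.get(assembly, StrandRelation.SAME)
            forward = (pair if relation is StrandRelation.SAME
                       else pair.complemented())
            locations.append(Location(
                assembly=assembly, chromosome=str(k + 1),
                position=1000 + 7 * (a + 1),
                illumina_forward=forward, strand_relation=relation,
                source="illumina"))
        out.append(Variant(name=name, illumina_top=pair, probe_seq=probe,
                           locations=locations))
    return out


def make_registry(spec: FixtureSpec,
                  out_dir=None) -> tuple[Registry, dict[str, Path]]:
    """Build a registry of ``n_snps`` variants (the two reference SNPs
    first) and, when ``out_dir`` is given, write matching Illumina CSV
    manifests (one per assembly) and optionally an Affymetrix annotation
    covering the first ``n_affymetrix_snps`` variants.

    Every generated probe has a decidable TOP/BOT walk by construction:
    for ambiguous SNPs the flank pair nearest the variant site is forced
    to one {A,T} and one {C,G} member, oriented per the drawn strand.
    """
    rng = _rng(spec, 1)
    registry = Registry(species=spec.species)
    variants = _reference_variants(spec.assemblies)
    n_random = spec.n_snps - len(variants)

    for i in range(n_random):
        name = f"SYN{i:06d}.1"
        ambiguous = rng.random() < spec.fraction_ambiguous
        pool = _AMBIGUOUS if ambiguous else _UNAMBIGUOUS
        top = AllelePair(*pool[rng.integers(len(pool))])
        probe_strand = Strand.TOP if rng.random() < 0.5 else Strand.BOT
        probe = _make_probe(rng, top, probe_strand, ambiguous,
                            spec.flank_length)
        assert designate_strand(probe) is probe_strand
        assert top_alleles(probe) == top

        chromosome = str(int(rng.integers(1, 27)))
        locations = []
        for a, assembly in enumerate(spec.assemblies):
            relation = (StrandRelation.OPPOSITE
                        if rng.random() < spec.fraction_opposite
                        else StrandRelation.SAME)
            forward = (top if relation is StrandRelation.SAME
                       else top.complemented())
            position = 10_000 * (i + 3) + int(rng.integers(0, 9_000))
            locations.append(Location(
                assembly=assembly, chromosome=chromosome, position=position,
                illumina_forward=forward, strand_relation=relation,
                source="illumina"))
        variants.append(Variant(name=name, illumina_top=top, probe_seq=probe,
                                locations=locations))

    for variant in variants:
        variant.chip_names.add(spec.chip_name)
        variant.aliases[spec.chip_name] = variant.name
        registry.add_variant(variant)

    paths: dict[str, Path] = {}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for assembly in spec.assemblies:
            path = out_dir / f"manifest_{spec.chip_name}_{assembly}.csv"
            _write_illumina_manifest(variants, assembly, path)
            paths[f"illumina:{assembly}"] = path
        if spec.n_affymetrix_snps > 0:
            path = out_dir / f"annotation_{spec.affymetrix_chip_name}.csv"
            _write_affymetrix_annotation(
                variants[:spec.n_affymetrix_snps], spec.dataset_assembly, path)
            paths["affymetrix"] = path
    return registry, paths


def _make_probe(rng, top: AllelePair, strand: Strand, ambiguous: bool,
                flank_length: int) -> str:
    bases = np.array(list("ACGT"))
    left = list(rng.choice(bases, flank_length))
    right = list(rng.choice(bases, flank_length))
    written = top if strand is Strand.TOP else top.complemented()
    if ambiguous:
        at = ("A", "T")[int(rng.integers(2))]
        cg = ("C", "G")[int(rng.integers(2))]
        if strand is Strand.TOP:
            left[-1], right[0] = at, cg
        else:
            left[-1], right[0] = cg, at
    return "".join(left) + f"[{written.first}/{written.second}]" + "".join(right)


def _write_illumina_manifest(variants, assembly: str, path: Path) -> None:
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["[Heading]"])
        writer.writerow(["Descriptor File Name", path.name])
        writer.writerow(["Genome Build", assembly])
        writer.writerow(["[Assay]"])
        writer.writerow(["IlmnID", "Name", "SNP", "SourceSeq", "Chr",
                         "MapInfo", "RefStrand"])
        for v in variants:
            loc = v.location(assembly, source="illumina")
            written = v.probe_seq[v.probe_seq.index("[") + 1:
                                  v.probe_seq.index("]")]
            strand = {StrandRelation.SAME: "+",
                      StrandRelation.OPPOSITE: "-"}.get(
                          loc.strand_relation if loc else
                          StrandRelation.UNKNOWN, "")
            writer.writerow([
                f"{v.name}-ilmn", v.name, f"[{written}]", v.probe_seq,
                loc.chromosome if loc else "0",
                loc.position if loc else 0, strand])
        writer.writerow(["[Controls]"])


def _write_affymetrix_annotation(variants, assembly: str, path: Path) -> None:
    with path.open("w", newline="") as fh:
        fh.write("#%create_date=synthetic\n#%genome-version=" + assembly + "\n")
        writer = csv.writer(fh, quoting=csv.QUOTE_ALL)
        writer.writerow(["Probe Set ID", "Affy SNP ID", "dbSNP RS ID",
                         "Chromosome", "Physical Position", "Flank",
                         "Allele A", "Allele B", "cust_snpid"])
        for k, v in enumerate(variants):
            loc = v.location(assembly, source="illumina")
            forward = (loc.illumina_forward if loc and loc.illumina_forward
                       else v.illumina_top)
            # the flank is written on the assembly forward strand: its
            # TOP/BOT designation must agree with the strand relation
            desired = (Strand.TOP if loc is None or
                       loc.strand_relation is StrandRelation.SAME
                       else Strand.BOT)
            flank = (v.probe_seq if designate_strand(v.probe_seq) is desired
                     else reverse_complement(v.probe_seq))
            writer.writerow([
                f"AX-{100000 + k}", f"Affx-{k}", "---",
                loc.chromosome if loc else "0",
                # Affymetrix mapping pipelines legitimately disagree with
                # Illumina by a few bases; model that divergence
                (loc.position + 2) if loc else 0,
                flank,
                forward.first, forward.second, v.name])


def make_dataset(registry: Registry, spec: FixtureSpec, out_dir=None,
                 fmt: str = "memory",
                 ) -> tuple[GenotypeDataset, Truth, dict[str, Path]]:
    """Generate a genotype dataset in ``spec.coding`` for the registry's
    SNPs, with planted duplicates, plus the ground truth.

    ``fmt``: "memory" (no files), "ped", "bed" or "report".
    """
    rng = _rng(spec, 2)
    variants = list(registry)
    assembly = spec.dataset_assembly
    n_base = spec.n_samples
    n_total = n_base + spec.n_duplicates
    if spec.n_duplicates > n_base:
        raise ValueError("cannot plant more duplicates than samples")

    freqs = rng.uniform(0.05, 0.95, size=len(variants))
    top_calls = np.empty((n_total, len(variants)), dtype="U2")
    for j, variant in enumerate(variants):
        pair = variant.illumina_top
        cells = np.array([pair.first * 2, pair.first + pair.second,
                          pair.second * 2], dtype="U2")
        dosage = rng.binomial(2, 1.0 - freqs[j], size=n_base)
        top_calls[:n_base, j] = cells[dosage]
    missing = rng.random((n_base, len(variants))) < spec.missing_rate
    top_calls[:n_base][missing] = MISSING_CELL

    samples = [SampleInfo(fid=f"FIX{i:03d}", iid=f"FIX{i:03d}")
               for i in range(n_base)]
    duplicate_pairs = []
    for d in range(spec.n_duplicates):
        row = n_base + d
        top_calls[row] = top_calls[d]
        perturb = rng.random(len(variants)) < spec.duplicate_missing_rate
        top_calls[row][perturb] = MISSING_CELL
        dup = SampleInfo(fid=f"FIX{d:03d}DUP", iid=f"FIX{d:03d}DUP")
        samples.append(dup)
        duplicate_pairs.append((samples[d].key, dup.key))

    # re-express the TOP truth in the requested coding
    coded = np.empty_like(top_calls)
    excluded: list[str] = []
    for j, variant in enumerate(variants):
        mapping = {}
        try:
            for cell in np.unique(top_calls[:, j]):
                out = inverse_convert_genotype(GenotypeCall(cell[0], cell[1]),
                                               spec.coding, variant, assembly)
                mapping[cell] = out.allele1 + out.allele2
        except UnresolvableStrandError:
            excluded.append(variant.name)
            coded[:, j] = MISSING_CELL
            continue
        for cell, value in mapping.items():
            coded[top_calls[:, j] == cell, j] = value

    snps = []
    for variant in variants:
        loc = variant.location(assembly)
        if spec.coding is Coding.ILLUMINA_AB:
            a1, a2 = "A", "B"
        elif spec.coding.is_forward and loc is not None and \
                loc.illumina_forward is not None:
            a1, a2 = loc.illumina_forward.first, loc.illumina_forward.second
        else:
            a1, a2 = variant.illumina_top.first, variant.illumina_top.second
        snps.append(SnpInfo(
            name=variant.name,
            chromosome=loc.chromosome if loc else "0",
            position=loc.position if loc else 0,
            allele1=a1, allele2=a2))
    dataset = GenotypeDataset(
        samples=samples, snps=snps, calls=coded, coding=spec.coding,
        assembly=assembly, chip_name=spec.chip_name,
        source=f"fixture-seed{spec.seed}")
    truth = Truth(coding=spec.coding, top_calls=top_calls,
                  duplicate_pairs=duplicate_pairs, excluded_snps=excluded,
                  allele1_freqs=freqs)

    paths: dict[str, Path] = {}
    if fmt != "memory":
        if out_dir is None:
            raise ValueError("out_dir required when writing files")
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        prefix = out_dir / "fixture"
        if fmt == "ped":
            ped, mp = write_plink_text(dataset, prefix)
            paths = {"ped": ped, "map": mp}
        elif fmt == "bed":
            bed, bim, fam = write_plink_binary(dataset, prefix)
            paths = {"bed": bed, "bim": bim, "fam": fam}
        elif fmt == "report":
            paths = {"report": write_illumina_report(
                dataset, prefix.with_suffix(".txt"))}
        else:
            raise ValueError(f"unknown format {fmt!r}")
    return dataset, truth, paths


def make_metadata(spec: FixtureSpec, dataset: GenotypeDataset,
                  out_path=None) -> list[dict]:
    """Sample metadata rows (and optionally a TSV) matching a generated
    dataset: breed/country assignments, GPS present with probability
    ``gps_probability``, breed purpose, one free-form extra column."""
    rng = _rng(spec, 3)
    rows = []
    for sample in dataset.samples:
        country_name, country = _COUNTRIES[rng.integers(len(_COUNTRIES))]
        breed, code = _BREEDS[rng.integers(len(_BREEDS))]
        has_gps = rng.random() < spec.gps_probability
        lon = float(np.round(rng.uniform(-10.0, 30.0), 5))
        lat = float(np.round(rng.uniform(35.0, 60.0), 5))
        purpose = _PURPOSES[rng.integers(len(_PURPOSES))]
        rows.append({
            "original_id": sample.iid,
            "breed": breed, "breed_code": code,
            "country": country, "country_name": country_name,
            "species": spec.species,
            "chip_name": spec.chip_name,
            "purpose": purpose,
            "location": (lon, lat) if has_gps else None,
            "extra": {"coat_color": ("white", "black", "brown")
                      [rng.integers(3)]},
        })
    if out_path is not None:
        out_path = Path(out_path)
        out_path.parent.mkdir(parents=True, exist_ok=True)
        with out_path.open("w") as fh:
            fh.write("original_id\tbreed\tbreed_code\tcountry\tspecies\t"
                     "chip_name\tpurpose\tlatitude\tlongitude\tcoat_color\n")
            for row in rows:
                lon_lat = row["location"]
                fh.write("\t".join([
                    row["original_id"], row["breed"], row["breed_code"],
                    row["country"], row["species"], row["chip_name"],
                    row["purpose"] or "",
                    f"{lon_lat[1]}" if lon_lat else "",
                    f"{lon_lat[0]}" if lon_lat else "",
                    row["extra"]["coat_color"]]) + "\n")
    return rows
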