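# snpharmony

Tools to standardize, convert and merge SNP-array genotype datasets for
diploid livestock — built around the sheep/goat use case, where decades of
published datasets mix chips (Illumina 50K/HD, Affymetrix custom panels),
genome assemblies (Oar_v3.1, Oar_v4.0, ARS1.2, CHIR_1.0) and genotype
codings, yet must be analyzed as one population-genetics resource.

## The problem

The same SNP arrives under three headaches:

1. **Names** — each manufacturer assigns its own identifier, so name
   matching alone cannot align panels.
2. **Coordinates** — positions change between assembly versions, and even
   on one assembly Illumina and Affymetrix mapping pipelines can disagree.
3. **Coding** — the identical genotype may be written as `A B`
   (manufacturer A/B symbols: the first/second allele of the manifest's
   SNP string), as `T C` (nucleotides on the forward strand of one
   particular assembly), or as `A G` (Illumina TOP).

snpharmony resolves all three with a **variant registry** (one document
per SNP holding every chip alias, probeset, rs ID and per-assembly
location) and the **Illumina TOP/BOT convention**, which derives strand
from the probe sequence itself and is therefore invariant across
assemblies:

- an unambiguous SNP containing A (A/G, A/C) is TOP; containing T
  (T/C, T/G) is BOT;
- an ambiguous SNP (A/T or C/G — its own complement) is resolved by
  walking flanking-base pairs equidistant from the variant site until one
  pair has exactly one base in {A,T} and one in {C,G}; the {A,T} member on
  the 5′ side means TOP, on the 3′ side BOT.

After conversion the only possible allele pairs are **[A/T], [C/G],
[A/G], [A/C]**. Conversion rules per source coding: A/B maps A↦first and
B↦second TOP allele; forward coding is kept (strand relation *same*) or
complemented per allele (*opposite*); ambiguous SNPs with unknown strand
relation cannot be verified and are excluded, following the FAO
genomic-characterization guideline.

Merged datasets take the **union** of SNPs ordered by position, with
cells off a sample's chip set missing — no MAF or missingness filtering.
The single filter offered is duplicate removal by **identity by state**:

IBS(i,j) = mean over jointly non-missing loci of (shared alleles,
counting multiplicity)/2 ∈ {0, ½, 1}; pairs with IBS ≥ 0.95 (default) are
flagged and the sample with fewer missing calls survives.

Samples get stable IDs of the form `UYOA-CRR-000003890`
(country + species code + breed code + 9-digit counter), and a schemaless
metadata store holds breed, country, GPS and free-form phenotype keys,
exportable as GeoJSON.

## Worked example

`examples/01_top_conversion.py` converts one animal's genotypes at the
unambiguous SNP DU186191_327.1 (TOP A/G) as delivered in four different
codings:

```
DU186191_327.1: TOP alleles A/G
   illumina_forward on Oar_v4.0: T C  ->  A G
        illumina_ab            : A B  ->  A G
       illumina_top            : G A  ->  G A
   illumina_forward on Oar_v3.1: T T  ->  A A
```

and at the ambiguous C/G SNP OAR1_103790218.1, where the forward strand
flips between assemblies, every delivery converges to `G G`. The other
examples cover registry construction from manifests
(`02_registry_and_manifests.py`), coding inference + merge + IBS dedup
(`03_merge_and_dedupe.py` — the planted duplicate is the only pair above
0.95, unrelated pairs score ≈0.61), and metadata/GeoJSON
(`04_metadata_and_geojson.py`).

The same functionality is exposed as a CLI:

```bash
snpharmony fixtures make --preset small --seed 4 --out fx/
snpharmony registry import-manifest fx/manifest_SyntheticChip50K_Oar_v4.0.csv \
    --registry reg.jsonl --chip SyntheticChip50K --assembly Oar_v4.0
snpharmony coding infer fx/fixture --registry reg.jsonl \
    --chip SyntheticChip50K --assembly Oar_v4.0
snpharmony run import.yaml --workdir work/   # idempotent pipeline
```

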