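# Methods

## Strand model

A SNP array probe identifies a biallelic variant `[X/Y]` within a short
flanking sequence. Because the probe may align to either genomic strand,
and alignments change between assembly versions, nucleotide codings tied
to an assembly's forward strand are unstable identifiers. The TOP/BOT
convention fixes orientation from the probe alone:

* unambiguous allele sets decide directly — {A,G} and {A,C} are TOP,
  {T,C} and {T,G} are BOT;
* ambiguous sets ({A,T}, {C,G}) are decided by the first equidistant
  flank pair (distance 1, 2, …) containing exactly one {A,T} and one
  {C,G} base: {A,T} member 5′ of the site ⇒ TOP, 3′ ⇒ BOT;
* if the flanks are exhausted the designation is *undetermined*. Such
  probes are importable but flagged, and their variants cannot support
  forward-coded conversion of ambiguous SNPs — matching the FAO guideline
  that an A/T or C/G SNP whose strand cannot be verified should be
  excluded before merging.

Only uppercase A/C/G/T flank bases are informative; N and IUPAC ambiguity
codes are skipped as non-informative pair members. `top_alleles` keeps
the written allele order on TOP probes (the A/B mapping depends on it)
and complements then alphabetizes on BOT probes. Two invariants are
enforced by property tests: reverse-complementing a probe flips the
designation and leaves the TOP allele set unchanged, and every conversion
result lies in the closed universe {A/T, C/G, A/G, A/C}.

## Conversion semantics

`convert_genotype(call, coding, variant, assembly)`:

* missing (`0 0`) propagates; half-calls (one missing allele) are
  normalized to fully missing with a logged warning, because the PLINK
  biallelic model defines no half-call semantics;
* A/B: A ↦ first TOP allele, B ↦ second;
* TOP: identity (validated against the variant's TOP alleles);
* forward codings: identity when the location's strand relation is
  *same*, per-allele complement when *opposite*; when *unknown*, an
  unambiguous SNP is resolved by comparing the observed allele set with
  the TOP set and its complement, while an ambiguous SNP raises an
  unresolvable-strand error (dataset-level conversion then excludes the
  SNP, action `excluded-ambiguous` in the report);
* `affymetrix_forward` behaves as forward coding but resolves alleles via
  Affymetrix-sourced locations.

Heterozygote allele order is preserved (`G A` stays `G A`); datasets are
never order-normalized. Any result outside the variant's TOP alleles is a
coding mismatch error, never silently coerced.

## Coding inference

For each candidate coding, concordance = fraction of non-missing calls
whose allele symbols are consistent with the registry's expectation
(A/B: {A,B}; TOP: the TOP set; forward: the location's forward set).
SNPs with no defined expectation under a coding (e.g. no location on the
dataset's assembly) are excluded from that coding's denominator. The
unique coding with concordance ≥ 0.99 wins; the threshold tolerates
genotyping error while rejecting wrong codings, whose concordance on
realistic panels falls near 0.5 (forward vs TOP with ~half opposite-strand
SNPs) or near 0 (A/B vs nucleotides). Ties — typically TOP vs forward
when every SNP happens to sit on the same strand — are broken only by
*discriminating* SNPs whose expected sets differ between the tied
codings; with no discriminating evidence the tie is returned and an
explicit override required rather than guessed.

## Registry

One document per SNP: canonical name, rs ID, chip names, per-chip
aliases, probe, TOP alleles, probesets, flags, free-form extras, and one
location per (assembly, imported source). Illumina- and
Affymetrix-sourced locations may disagree on the same assembly and are
stored side by side; position lookup prefers the Illumina mapping
deterministically. Re-importing identical records is a no-op; a second
chip's record for the same SNP merges aliases and locations into the
existing document; conflicting TOP alleles are kept under
`extra["top_conflicts"]` with a `top_conflict` flag instead of picking a
winner. Persistence is a JSON-lines file, one registry per species.
Coordinates are 1-based as in PLINK MAP/BIM; unmapped is chromosome "0",
position 0.

## Merge, IDs and duplicates

Merging requires TOP coding on a single assembly. SNP names are unified
to registry canonical names through chip aliases; the output SNP set is
the union, ordered by (chromosome, position) with unmapped SNPs last by
name; source calls are copied verbatim and off-chip cells are missing.
No missingness or MAF filtering is applied — panel-wide MAF filtering
would discard exactly the rare variation that makes local breeds
interesting, and which alleles are "minor" depends on the sample subset.

Stable sample IDs render as `^[A-Z]{2}[A-Z]{2}-[A-Z0-9]{3}-[0-9]{9}$`
(country alpha-2, species code OA/CH, breed code, counter). One counter
per species spans all datasets; assignment state is persisted so replays
return existing IDs without advancing the counter.

Pairwise IBS is computed on the intersection of two samples' non-missing
loci as the mean per-locus shared-allele fraction, equivalently
`1 − |d_i − d_j|/2` on allele dosages. `find_duplicates` examines all
unordered pairs (or only between-dataset pairs with `mode="between"`,
since the duplicate scenario of record is overlap between published
datasets); pairs at or above the threshold (default 0.95) are flagged
with a designated survivor — fewer missing calls, ties to the earlier
dataset — and returned as a report; removal is a separate explicit step,
never applied silently.

## File formats

PLINK text (PED/MAP) and binary (BED/BIM/FAM) are read and written by
this package; the BED writer follows the published layout exactly (magic
`6C 1B`, SNP-major `01`, 2-bit codes 00/01/10/11 = hom-A1 / missing /
het / hom-A2, four samples per byte low bits first, per-SNP byte
padding) and is deterministic, so write∘read∘write is byte-identical.
BIM columns are chrom, name, cM (written 0), bp, allele1, allele2 with
allele1 = the first TOP allele after conversion. Illumina Final Reports
are parsed from their `[Data]` section with Top/Forward/AB allele column
pairs (others rejected loudly); Illumina CSV manifests from the
`[Assay]` section; Affymetrix annotations from header-commented CSV.
Affymetrix intensity (CEL) files are out of scope — the supported
Affymetrix genotype input is a probeset × sample calls table (0/1/2/−1
dosages or nucleotide pairs). The Affymetrix flank is taken to be written
on the assembly forward strand, so its TOP/BOT designation fixes the
strand relation; a contradiction with the annotated alleles is flagged
rather than resolved.

## Synthetic-data generator

`fixtures` emulates the study conditions end to end: chip manifests with
decidable probe walks (flanks of 10 bases per side, the pair nearest an
ambiguous site forced to one {A,T} and one {C,G} member), per-assembly
locations with strand relations drawn opposite with probability 0.5,
Hardy–Weinberg genotypes at allele frequencies uniform on [0.05, 0.95],
2% missing calls, metadata with 80% GPS coverage, and duplicates planted
as copies with 2% of calls additionally set missing. Two reference SNPs
with fixed conversion behaviour are always included: DU186191_327.1
(TOP A/G, forward opposite to TOP on both Oar_v3.1 and Oar_v4.0) and the
ambiguous OAR1_103790218.1 (TOP C/G, opposite on Oar_v3.1, same on
Oar_v4.0); their probe flanks are synthetic, constructed to reproduce
those designations. All randomness flows from one integer seed through
fixed-offset substreams, so adding an artifact never shifts existing
outputs and equal seeds give byte-identical files.

What the generator does *not* emulate: linkage disequilibrium and
population structure (loci and samples are independent), genotyping
error beyond missingness, pedigrees, sex chromosomes, tri-allelic sites
and indels. Passing tests therefore demonstrate the correctness of the
harmonization algebra and plumbing, not robustness to structured real
data — with one deliberate exception: duplicate detection is validated
against independent-locus genotypes, where unrelated-pair IBS
concentrates near 0.7, and real LD would mainly widen that distribution,
which the 0.95 threshold accommodates.

Validation problem sizes are 100 SNPs × 20 samples for coding-inference
recovery (20 seeds × 3 codings) and 1000 SNPs × 20 samples for duplicate
detection (10 seeds): at 1000 independent loci the gap between
duplicate-pair IBS (≈1) and the unrelated-pair distribution exceeds
thirty standard deviations, so sensitivity and specificity are both
structural rather than marginal.

## Pipeline

`run_import` executes an ordered YAML step list (manifest imports,
dataset imports with inference + conversion + ID assignment, merge,
dedupe). Each completed step is recorded with a SHA-256 digest of its
parameters and input files; unchanged steps are skipped on re-run, a
failed step halts the run leaving prior steps valid, and all outputs are
written with sorted keys and no timestamps, making reruns byte-identical.
The release stamp is a static semantic-version JSON for the same reason:
a wall-clock stamp would break the byte-identity invariant.

## Known limitations

* Breed codes are opaque 3-character tokens supplied at import; no breed
  ontology is enforced, and phenotype keys are free-form (no PATO
  mapping).
* Country normalization covers a built-in table of common study
  countries plus ISO alpha-2 passthrough.
* No VCF import/export, no probe re-alignment against genome FASTA, no
  live dbSNP/EVA queries (external IDs are stored, not fetched), no
  kinship estimation beyond IBS, no imputation.
* Pairwise IBS is O(n²·m); fine at the thousands-of-samples scale this
  package targets, not optimized for biobank scale.
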