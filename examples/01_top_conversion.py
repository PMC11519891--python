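"""Convert genotypes from any source coding into Illumina TOP.

Builds the registry entries for two reference SNPs — the unambiguous
DU186191_327.1 (TOP A/G) and the ambiguous OAR1_103790218.1 (TOP C/G) —
and converts the same animals' genotypes as delivered in forward, A/B and
TOP codings.  After conversion all datasets agree on one coding that does
not change when the genome assembly does.
"""

from snpharmony import Coding, FixtureSpec, convert_genotype, make_registry

registry, _ = make_registry(FixtureSpec(n_snps=2, seed=0))
du = registry.get("DU186191_327.1")
oar = registry.get("OAR1_103790218.1")

print(f"{du.name}: TOP alleles {du.illumina_top}")
rows = [
    (("T", "C"), Coding.ILLUMINA_FORWARD, "Oar_v4.0"),
    (("A", "B"), Coding.ILLUMINA_AB, None),
    (("G", "A"), Coding.ILLUMINA_TOP, None),
    (("T", "T"), Coding.ILLUMINA_FORWARD, "Oar_v3.1"),
]
for call, coding, assembly in rows:
    top = convert_genotype(call, coding, du, assembly)
    src = f"{call[0]} {call[1]}"
    where = f" on {assembly}" if assembly else ""
    print(f"  {coding.value:>17}{where:>12}: {src}  ->  {top}")

print(f"\n{oar.name}: TOP alleles {oar.illumina_top} (ambiguous C/G SNP)")
rows = [
    (("G", "G"), Coding.ILLUMINA_FORWARD, "Oar_v4.0"),
    (("B", "B"), Coding.ILLUMINA_AB, None),
    (("G", "G"), Coding.ILLUMINA_TOP, None),
    (("C", "C"), Coding.ILLUMINA_FORWARD, "Oar_v3.1"),
]
for call, coding, assembly in rows:
    top = convert_genotype(call, coding, oar, assembly)
    src = f"{call[0]} {call[1]}"
    where = f" on {assembly}" if assembly else ""
    print(f"  {coding.value:>17}{where:>12}: {src}  ->  {top}")

print("\nEvery row is the same animal's genotype at the same SNP; the TOP")
print("column is identical regardless of the coding or assembly it came in.")
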