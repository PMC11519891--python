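"""TOP/BOT designation, complement arithmetic and genotype conversion."""

import re

import pytest
from hypothesis import given, strategies as st

from snpharmony import (
    AllelePair,
    Coding,
    GenotypeCall,
    Strand,
    complement,
    convert_genotype,
    designate_strand,
    inverse_convert_genotype,
    is_ambiguous,
    reverse_complement,
    top_alleles,
)
from snpharmony.errors import (
    CodingMismatchError,
    ProbeParseError,
    UndeterminedStrandError,
    UnresolvableStrandError,
)

PAIRS = [(x, y) for x in "ACGT" for y in "ACGT" if x != y]


def oracle_designation(probe: str) -> str:
    """Independent hand-walk reimplementation of the TOP/BOT convention,
    used as the oracle for designate_strand."""
    m = re.match(r"^(.*)\[([ACGT])/([ACGT])\](.*)$", probe)
    left, x, y, right = m.groups()
    alleles = {x, y}
    if alleles not in ({"A", "T"}, {"C", "G"}):
        return "TOP" if "A" in alleles else "BOT"
    left = left[::-1]  # walk outwards
    for five, three in zip(left, right):
        informative = {five, three} <= set("ACGT")
        if informative and (five in "AT") != (three in "AT"):
            return "TOP" if five in "AT" else "BOT"
    return "undetermined"


@st.composite
def probes(draw):
    flank = st.text(alphabet="ACGTN", max_size=8)
    x, y = draw(st.sampled_from(PAIRS))
    return f"{draw(flank)}[{x}/{y}]{draw(flank)}"


class TestComplement:
    @given(st.sampled_from("ACGT"))
    def test_involution(self, base):
        assert complement(complement(base)) == base

    def test_pairing(self):
        assert complement("A") == "T"
        assert complement("C") == "G"

    @pytest.mark.parametrize("bad", ["N", "a", "0", "-"])
    def test_rejects_non_nucleotides(self, bad):
        with pytest.raises(ValueError):
            complement(bad)

    def test_pair_complement(self):
        # an A/G polymorphism read from the other strand is T/C
        assert AllelePair("A", "G").complemented() == AllelePair("T", "C")


class TestAmbiguity:
    @pytest.mark.parametrize("pair,expected", [
        (("A", "T"), True), (("T", "A"), True),
        (("C", "G"), True), (("G", "C"), True),
        (("A", "G"), False), (("A", "C"), False),
        (("T", "C"), False), (("T", "G"), False),
    ])
    def test_pairs(self, pair, expected):
        assert is_ambiguous(AllelePair(*pair)) is expected


class TestDesignateStrand:
    @pytest.mark.parametrize("probe,expected", [
        ("NN[A/G]NN", Strand.TOP),
        ("NN[T/C]NN", Strand.BOT),
        ("T[A/T]C", Strand.TOP),
        ("G[A/T]A", Strand.BOT),       # reverse complement of the above
        ("AT[C/G]AT", Strand.UNDETERMINED),  # every pair same-class
        ("[C/G]", Strand.UNDETERMINED),      # empty flanks
        ("NAT[C/G]GCN", Strand.TOP),   # decided at distance 1 (T vs G)
    ])
    def test_examples(self, probe, expected):
        assert designate_strand(probe) is expected

    @given(probes())
    def test_matches_hand_walk_oracle(self, probe):
        assert designate_strand(probe).value == oracle_designation(probe)

    @given(probes())
    def test_reverse_complement_flips_designation(self, probe):
        forward = designate_strand(probe)
        flipped = designate_strand(reverse_complement(probe))
        if forward is Strand.UNDETERMINED:
            assert flipped is Strand.UNDETERMINED
        else:
            assert {forward, flipped} == {Strand.TOP, Strand.BOT}

    @pytest.mark.parametrize("bad", ["ACGT", "A[C/G]T[A/G]C", "[C/G"])
    def test_rejects_malformed_site(self, bad):
        with pytest.raises(ProbeParseError):
            designate_strand(bad)


class TestTopAlleles:
    @pytest.mark.parametrize("probe,expected", [
        ("NN[T/C]NN", ("A", "G")),  # BOT: complement then order
        ("NN[A/G]NN", ("A", "G")),  # TOP: as written
        ("NN[G/A]NN", ("G", "A")),  # TOP keeps written order
        ("G[A/T]A", ("A", "T")),    # self-complementary allele set
        ("T[A/T]C", ("A", "T")),
    ])
    def test_examples(self, probe, expected):
        assert top_alleles(probe) == AllelePair(*expected)

    @given(probes())
    def test_invariant_under_reverse_complement(self, probe):
        if designate_strand(probe) is Strand.UNDETERMINED:
            return
        assert top_alleles(probe).as_set == \
            top_alleles(reverse_complement(probe)).as_set

    @given(probes())
    def test_result_is_in_top_universe(self, probe):
        if designate_strand(probe) is Strand.UNDETERMINED:
            return
        assert top_alleles(probe).as_set in {
            frozenset("AT"), frozenset("CG"), frozenset("AG"), frozenset("AC")}

    def test_undetermined_raises(self):
        with pytest.raises(UndeterminedStrandError):
            top_alleles("AT[C/G]AT")


class TestGenotypeCall:
    def test_half_call_normalized_to_missing(self):
        assert GenotypeCall("A", "0").is_missing
        assert GenotypeCall("0", "G") == GenotypeCall("0", "0")


class TestConvertGenotype:
    """The two published conversion examples: DU186191_327.1 (TOP A/G,
    forward strand opposite to TOP on both assemblies) and the ambiguous
    OAR1_103790218.1 (TOP C/G, opposite on Oar_v3.1, same on Oar_v4.0)."""

    @pytest.mark.parametrize("call,coding,assembly,expected", [
        (("T", "C"), Coding.ILLUMINA_FORWARD, "Oar_v4.0", "A G"),
        (("A", "B"), Coding.ILLUMINA_AB, None, "A G"),
        (("G", "A"), Coding.ILLUMINA_TOP, None, "G A"),
        (("T", "T"), Coding.ILLUMINA_FORWARD, "Oar_v3.1", "A A"),
    ])
    def test_unambiguous_snp(self, reference_variants, call, coding,
                             assembly, expected):
        du, _ = reference_variants
        assert str(convert_genotype(call, coding, du, assembly)) == expected

    @pytest.mark.parametrize("call,coding,assembly", [
        (("G", "G"), Coding.ILLUMINA_FORWARD, "Oar_v4.0"),
        (("B", "B"), Coding.ILLUMINA_AB, None),
        (("G", "G"), Coding.ILLUMINA_TOP, None),
        (("C", "C"), Coding.ILLUMINA_FORWARD, "Oar_v3.1"),
    ])
    def test_ambiguous_snp_all_paths_give_gg(self, reference_variants, call,
                                             coding, assembly):
        _, oar = reference_variants
        assert str(convert_genotype(call, coding, oar, assembly)) == "G G"

    @pytest.mark.parametrize("coding", list(Coding))
    def test_missing_propagates(self, reference_variants, coding):
        du, _ = reference_variants
        out = convert_genotype(("0", "0"), coding, du, "Oar_v4.0")
        assert out.is_missing

    def test_top_input_is_fixed_point(self, reference_variants):
        du, _ = reference_variants
        once = convert_genotype(("G", "A"), Coding.ILLUMINA_TOP, du)
        twice = convert_genotype(once, Coding.ILLUMINA_TOP, du)
        assert once == twice == GenotypeCall("G", "A")

    @pytest.mark.parametrize("coding,assembly", [
        (Coding.ILLUMINA_AB, None),
        (Coding.ILLUMINA_FORWARD, "Oar_v3.1"),
        (Coding.ILLUMINA_FORWARD, "Oar_v4.0"),
    ])
    def test_round_trip_identity(self, reference_variants, coding, assembly):
        du, oar = reference_variants
        for variant in (du, oar):
            pair = variant.illumina_top
            for call in [(pair.first, pair.first), (pair.first, pair.second),
                         (pair.second, pair.first), (pair.second, pair.second)]:
                coded = inverse_convert_genotype(call, coding, variant, assembly)
                back = convert_genotype(coded, coding, variant, assembly)
                assert back == GenotypeCall(*call)

    def test_mismatching_alleles_rejected(self, reference_variants):
        du, _ = reference_variants  # TOP A/G
        with pytest.raises(CodingMismatchError):
            convert_genotype(("C", "C"), Coding.ILLUMINA_TOP, du)
        with pytest.raises(CodingMismatchError):
            convert_genotype(("A", "A"), Coding.ILLUMINA_FORWARD, du,
                             "Oar_v4.0")  # forward is T/C there

    def test_ambiguous_forward_unknown_strand_unresolvable(self):
        from snpharmony import Location, StrandRelation, Variant

        variant = Variant(
            name="amb", illumina_top=AllelePair("C", "G"),
            locations=[Location(assembly="Oar_v4.0", chromosome="1",
                                position=10,
                                strand_relation=StrandRelation.UNKNOWN)])
        with pytest.raises(UnresolvableStrandError):
            convert_genotype(("C", "C"), Coding.ILLUMINA_FORWARD, variant,
                             "Oar_v4.0")

    def test_unambiguous_forward_unknown_strand_resolved_by_alleles(self):
        from snpharmony import Location, StrandRelation, Variant

        variant = Variant(
            name="unamb", illumina_top=AllelePair("A", "G"),
            locations=[Location(assembly="Oar_v4.0", chromosome="1",
                                position=10,
                                strand_relation=StrandRelation.UNKNOWN)])
        # T/C can only be the opposite strand of A/G
        out = convert_genotype(("T", "C"), Coding.ILLUMINA_FORWARD, variant,
                               "Oar_v4.0")
        assert str(out) == "A G"
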