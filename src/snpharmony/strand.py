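"""Illumina TOP/BOT strand algebra and genotype-coding conversion.

SNP-array genotypes arrive in several codings that all describe the same
polymorphism:

* **A/B** — manufacturer symbols: A and B are the first and second allele of
  the SNP string recorded in the chip manifest, not nucleotides.
* **forward** — nucleotides on the forward strand of one specific reference
  assembly; the meaning changes whenever the assembly changes.
* **TOP** — nucleotides in Illumina's TOP/BOT convention, which is derived
  from the probe sequence alone and is therefore invariant across
  assemblies.  After TOP conversion the only possible allele pairs are
  A/T, C/G, A/G and A/C.

The TOP/BOT designation rules implemented by :func:`designate_strand`:

* an unambiguous SNP containing A (A/G, A/C) is TOP; containing T
  (T/C, T/G) is BOT;
* an ambiguous SNP (A/T, C/G) is resolved by walking flanking-base pairs
  equidistant from the variant site (distance 1, 2, ...) until a pair has
  exactly one base in {A, T} and one in {C, G}; if the {A,T} member sits on
  the 5' side the probe is TOP, on the 3' side BOT;
* if the flanks are exhausted first the designation is undetermined.

Only uppercase A/C/G/T flanking bases are informative during the walk;
anything else (N, IUPAC ambiguity codes) is skipped.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass
from typing import TYPE_CHECKING

from .errors import (
    CodingMismatchError,
    ProbeParseError,
    UndeterminedStrandError,
    UnresolvableStrandError,
)

if TYPE_CHECKING:  # pragma: no cover
    from .registry import Variant

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_NUCLEOTIDES = frozenset("ACGT")
MISSING = "0"

#: the closed set of allele pairs that can result from TOP conversion
TOP_PAIRS = frozenset({frozenset("AT"), frozenset("CG"),
                       frozenset("AG"), frozenset("AC")})


def complement(base: str) -> str:
    """Watson-Crick complement of a single uppercase nucleotide."""
    try:
        return _COMPLEMENT[base]
    except KeyError:
        raise ValueError(f"not a nucleotide: {base!r}") from None


def reverse_complement(probe: str) -> str:
    """Reverse complement of a probe string, preserving one ``[X/Y]`` site."""
    left, x, y, right = _parse_probe(probe)

    def rc(seq: str) -> str:
        return "".join(_COMPLEMENT.get(b, b) for b in reversed(seq))

    return f"{rc(right)}[{complement(x)}/{complement(y)}]{rc(left)}"


@dataclass(frozen=True)
class AllelePair:
    """An ordered pair of distinct nucleotides.

    Order is meaningful: A/B coding maps A to ``first`` and B to ``second``.
    Strand arithmetic (complement, ambiguity) acts on the unordered set.
    """

    first: str
    second: str

    def __post_init__(self) -> None:
        if self.first not in _NUCLEOTIDES or self.second not in _NUCLEOTIDES:
            raise ValueError(f"alleles must be A/C/G/T, got {self.first}/{self.second}")
        if self.first == self.second:
            raise ValueError(f"alleles must differ, got {self.first}/{self.second}")

    @property
    def as_set(self) -> frozenset:
        return frozenset((self.first, self.second))

    def complemented(self) -> "AllelePair":
        return AllelePair(complement(self.first), complement(self.second))

    def __str__(self) -> str:
        return f"{self.first}/{self.second}"

    @classmethod
    def from_string(cls, text: str) -> "AllelePair":
        """Parse ``"A/G"`` or ``"[A/G]"``."""
        m = re.fullmatch(r"\[?([ACGT])/([ACGT])\]?", text.strip())
        if not m:
            raise ValueError(f"cannot parse allele pair: {text!r}")
        return cls(m.group(1), m.group(2))


def is_ambiguous(pair: AllelePair) -> bool:
    """True iff the pair is its own complement (A/T or C/G), so strand
    cannot be told from the alleles alone."""
    return pair.as_set in (frozenset("AT"), frozenset("CG"))


class Strand(str, enum.Enum):
    TOP = "TOP"
    BOT = "BOT"
    UNDETERMINED = "undetermined"


class Coding(str, enum.Enum):
    """Genotype coding conventions a dataset may arrive in."""

    ILLUMINA_TOP = "illumina_top"
    ILLUMINA_FORWARD = "illumina_forward"
    ILLUMINA_AB = "illumina_ab"
    AFFYMETRIX_FORWARD = "affymetrix_forward"

    @property
    def is_forward(self) -> bool:
        return self in (Coding.ILLUMINA_FORWARD, Coding.AFFYMETRIX_FORWARD)

    @property
    def location_source(self) -> str:
        """Which imported manifest source resolves forward alleles."""
        return "affymetrix" if self is Coding.AFFYMETRIX_FORWARD else "illumina"


class StrandRelation(str, enum.Enum):
    """Orientation of an assembly's forward coding relative to TOP."""

    SAME = "same"
    OPPOSITE = "opposite"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class GenotypeCall:
    """A diploid call: two symbols from {A,C,G,T,0} (or {A,B,0} in A/B
    coding), 0 meaning missing.

    Half-calls (exactly one missing symbol) are normalized to fully missing;
    neither the PLINK biallelic model nor this package defines semantics for
    them.
    """

    allele1: str
    allele2: str

    def __post_init__(self) -> None:
        if (self.allele1 == MISSING) != (self.allele2 == MISSING):
            logger.warning("half-call %s %s normalized to missing",
                           self.allele1, self.allele2)
            object.__setattr__(self, "allele1", MISSING)
            object.__setattr__(self, "allele2", MISSING)

    @property
    def is_missing(self) -> bool:
        return self.allele1 == MISSING

    @property
    def as_set(self) -> frozenset:
        return frozenset((self.allele1, self.allele2))

    def __str__(self) -> str:
        return f"{self.allele1} {self.allele2}"


MISSING_CALL = GenotypeCall(MISSING, MISSING)

_PROBE_RE = re.compile(r"^([A-Za-z.\-]*)\[([ACGT])/([ACGT])\]([A-Za-z.\-]*)$")


def _parse_probe(probe: str):
    if probe.count("[") != 1 or probe.count("]") != 1:
        raise ProbeParseError(f"probe must contain exactly one [X/Y] site: {probe!r}")
    m = _PROBE_RE.match(probe.strip())
    if not m:
        raise ProbeParseError(f"cannot parse probe: {probe!r}")
    return m.group(1), m.group(2), m.group(3), m.group(4)


def designate_strand(probe: str) -> Strand:
    """TOP/BOT designation of a probe sequence with one ``[X/Y]`` site."""
    left, x, y, right = _parse_probe(probe)
    pair = AllelePair(x, y)
    if not is_ambiguous(pair):
        return Strand.TOP if "A" in pair.as_set else Strand.BOT
    # ambiguous SNP: walk equidistant flank pairs outwards
    for k in range(1, max(len(left), len(right)) + 1):
        five = left[-k] if k <= len(left) else None
        three = right[k - 1] if k <= len(right) else None
        if five not in _NUCLEOTIDES or three not in _NUCLEOTIDES:
            continue
        five_at = five in "AT"
        three_at = three in "AT"
        if five_at == three_at:  # same class: uninformative
            continue
        return Strand.TOP if five_at else Strand.BOT
    return Strand.UNDETERMINED


def top_alleles(probe: str) -> AllelePair:
    """TOP-orientation alleles of a probe.

    TOP probes keep the ``[X/Y]`` alleles as written; BOT probes are
    complemented per allele and then ordered alphabetically so the pair is
    one of A/T, C/G, A/G, A/C.
    """
    strand = designate_strand(probe)
    if strand is Strand.UNDETERMINED:
        raise UndeterminedStrandError(
            f"cannot determine TOP/BOT for probe {probe!r}; curate manually")
    _, x, y, _ = _parse_probe(probe)
    if strand is Strand.BOT:
        x, y = complement(x), complement(y)
        if x > y:
            x, y = y, x
    return AllelePair(x, y)


def _as_call(call) -> GenotypeCall:
    if isinstance(call, GenotypeCall):
        return call
    return GenotypeCall(call[0], call[1])


def convert_genotype(call, coding: Coding, variant: "Variant",
                     assembly: str | None = None) -> GenotypeCall:
    """Convert one genotype call into Illumina TOP coding.

    Parameters
    ----------
    call
        A :class:`GenotypeCall` or 2-sequence of symbols.
    coding
        The source coding of ``call``.
    variant
        Registry variant supplying TOP alleles and per-assembly locations.
    assembly
        Required for forward codings: which assembly's forward strand the
        call is expressed on.

    Heterozygote allele order is preserved (``G A`` stays ``G A``).
    Missing propagates.  The result's alleles must be a subset of the
    variant's TOP alleles, otherwise :class:`CodingMismatchError` is raised.
    """
    call = _as_call(call)
    if call.is_missing:
        return MISSING_CALL
    coding = Coding(coding)
    top = variant.illumina_top

    if coding is Coding.ILLUMINA_AB:
        mapping = {"A": top.first, "B": top.second}
        bad = call.as_set - set(mapping)
        if bad:
            raise CodingMismatchError(
                f"{variant.name}: A/B call {call} has symbols {sorted(bad)}")
        out = GenotypeCall(mapping[call.allele1], mapping[call.allele2])
    elif coding is Coding.ILLUMINA_TOP:
        out = call
    else:  # forward codings
        if assembly is None:
            raise ValueError("assembly is required for forward codings")
        loc = variant.location(assembly, source=coding.location_source)
        relation = loc.strand_relation if loc is not None else StrandRelation.UNKNOWN
        if relation is StrandRelation.SAME:
            out = call
        elif relation is StrandRelation.OPPOSITE:
            out = GenotypeCall(complement(call.allele1), complement(call.allele2))
        else:  # unknown relation
            if is_ambiguous(top):
                raise UnresolvableStrandError(
                    f"{variant.name}: ambiguous SNP ({top}) in forward coding "
                    f"with unknown strand relation on {assembly}")
            if call.as_set <= top.as_set:
                out = call
            elif call.as_set <= {complement(b) for b in top.as_set}:
                out = GenotypeCall(complement(call.allele1),
                                   complement(call.allele2))
            else:
                raise CodingMismatchError(
                    f"{variant.name}: forward call {call} matches neither "
                    f"TOP {top} nor its complement")
    if not out.as_set <= top.as_set:
        raise CodingMismatchError(
            f"{variant.name}: converted call {out} outside TOP alleles {top}")
    return out


def inverse_convert_genotype(call, coding: Coding, variant: "Variant",
                             assembly: str | None = None) -> GenotypeCall:
    """Re-express a TOP call in another coding (the inverse of
    :func:`convert_genotype`); used by the synthetic-data generator."""
    call = _as_call(call)
    if call.is_missing:
        return MISSING_CALL
    coding = Coding(coding)
    top = variant.illumina_top
    if not call.as_set <= top.as_set:
        raise CodingMismatchError(
            f"{variant.name}: TOP call {call} outside TOP alleles {top}")
    if coding is Coding.ILLUMINA_TOP:
        return call
    if coding is Coding.ILLUMINA_AB:
        mapping = {top.first: "A", top.second: "B"}
        return GenotypeCall(mapping[call.allele1], mapping[call.allele2])
    if assembly is None:
        raise ValueError("assembly is required for forward codings")
    loc = variant.location(assembly, source=coding.location_source)
    relation = loc.strand_relation if loc is not None else StrandRelation.UNKNOWN
    if relation is StrandRelation.SAME:
        return call
    if relation is StrandRelation.OPPOSITE:
        return GenotypeCall(complement(call.allele1), complement(call.allele2))
    raise UnresolvableStrandError(
        f"{variant.name}: unknown strand relation on {assembly}")
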