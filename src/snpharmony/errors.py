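"""Exception hierarchy.

Everything raised on purpose by this package derives from
:class:`SnpHarmonyError`, so callers can catch one type at pipeline level.
"""


class SnpHarmonyError(Exception):
    """Base class for all snpharmony errors."""


class ProbeParseError(SnpHarmonyError):
    """Probe/SNP string does not contain exactly one ``[X/Y]`` site."""


class UndeterminedStrandError(SnpHarmonyError):
    """TOP/BOT designation could not be decided; manual curation required."""


class UnresolvableStrandError(SnpHarmonyError):
    """Ambiguous (A/T or C/G) SNP in forward coding with unknown strand
    relation: cannot be converted; the caller may exclude the SNP."""


class CodingMismatchError(SnpHarmonyError):
    """A genotype call contains alleles outside the expected set for the
    declared coding."""


class UnrecognizedCodingError(SnpHarmonyError):
    """No candidate coding reached the concordance threshold."""

    def __init__(self, message, concordance=None):
        super().__init__(message)
        self.concordance = dict(concordance or {})


class AliasConflictError(SnpHarmonyError):
    """A chip alias is already bound to a different variant."""


class LocationConflictError(SnpHarmonyError):
    """Two different locations claim the same (assembly, source) slot."""


class MergeConflictError(SnpHarmonyError):
    """The same canonical SNP carries conflicting TOP alleles across the
    datasets being merged."""


class FormatError(SnpHarmonyError):
    """A file does not conform to the declared format."""
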