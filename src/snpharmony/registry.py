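"""Multi-chip, multi-assembly variant registry.

One SNP is typically carried by several chips under different names and is
mapped to different coordinates on different genome assemblies (and
occasionally to different coordinates on the *same* assembly when Illumina
and Affymetrix mapping pipelines disagree).  The registry makes one SNP
addressable under any of those identities: by canonical name, by any chip
alias, by rs ID, and by (assembly, chromosome, position).

All information about a SNP lives in a single :class:`Variant` record; the
registry is an in-memory collection of those records with lookup indexes,
persisted as one JSON document per line (schemaless ``extra`` preserved).
A registry holds one species (sheep and goat registries are kept separate).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

from .errors import AliasConflictError, LocationConflictError
from .strand import AllelePair, StrandRelation, complement

logger = logging.getLogger(__name__)

#: unmapped convention follows PLINK: chromosome "0", position 0
UNMAPPED_CHROM = "0"
UNMAPPED_POS = 0

#: deterministic preference order when several imported sources map the
#: same variant on one assembly
_SOURCE_PREFERENCE = ("illumina", "affymetrix")


@dataclass(frozen=True)
class Location:
    """Assembly-specific facts about a variant.

    ``strand_relation`` records the orientation of this assembly's forward
    coding relative to TOP: if ``same``, ``illumina_forward`` equals the
    variant's TOP alleles; if ``opposite``, their per-base complement.
    ``source`` is the manifest family the mapping came from (illumina or
    affymetrix); divergent mappings from different sources coexist as
    distinct locations.
    """

    assembly: str
    chromosome: str = UNMAPPED_CHROM
    position: int = UNMAPPED_POS
    illumina_forward: AllelePair | None = None
    strand_relation: StrandRelation = StrandRelation.UNKNOWN
    source: str = "illumina"

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError("position must be >= 0")
        if (self.position == UNMAPPED_POS) != (self.chromosome == UNMAPPED_CHROM):
            raise ValueError(
                f"position 0 iff chromosome '0', got {self.chromosome}:{self.position}")

    @property
    def is_mapped(self) -> bool:
        return self.chromosome != UNMAPPED_CHROM

    @property
    def key(self):
        return (self.assembly, self.source)


@dataclass
class Variant:
    """One SNP with all its identities across chips and assemblies."""

    name: str
    illumina_top: AllelePair
    rs_id: str | None = None
    chip_names: set[str] = field(default_factory=set)
    aliases: dict[str, str] = field(default_factory=dict)  # chip -> name on chip
    probe_seq: str | None = None
    probesets: list[tuple[str, str]] = field(default_factory=list)
    locations: list[Location] = field(default_factory=list)
    flags: set[str] = field(default_factory=set)
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("variant name must be nonempty")
        if self.illumina_top.as_set not in {frozenset("AT"), frozenset("CG"),
                                            frozenset("AG"), frozenset("AC")}:
            raise ValueError(
                f"{self.name}: TOP alleles must be one of A/T, C/G, A/G, A/C, "
                f"got {self.illumina_top}")
        seen = set()
        for loc in self.locations:
            if loc.key in seen:
                raise LocationConflictError(
                    f"{self.name}: duplicate location for {loc.key}")
            seen.add(loc.key)
            _check_forward(self.name, self.illumina_top, loc)

    def location(self, assembly: str, source: str | None = None) -> Location | None:
        """The location on ``assembly``; with ``source=None`` the
        Illumina-sourced mapping wins deterministically over Affymetrix."""
        candidates = [l for l in self.locations if l.assembly == assembly]
        if source is not None:
            for loc in candidates:
                if loc.source == source:
                    return loc
            return None
        candidates.sort(key=lambda l: (_source_rank(l.source), l.source))
        return candidates[0] if candidates else None

    def name_on_chip(self, chip_name: str) -> str:
        return self.aliases.get(chip_name, self.name)


def _source_rank(source: str) -> int:
    try:
        return _SOURCE_PREFERENCE.index(source)
    except ValueError:
        return len(_SOURCE_PREFERENCE)


def _check_forward(name: str, top: AllelePair, loc: Location) -> None:
    if loc.illumina_forward is None:
        return
    if loc.strand_relation is StrandRelation.SAME:
        expect = top.as_set
    elif loc.strand_relation is StrandRelation.OPPOSITE:
        expect = frozenset(complement(b) for b in top.as_set)
    else:
        return
    if loc.illumina_forward.as_set != expect:
        raise ValueError(
            f"{name}: forward alleles {loc.illumina_forward} on {loc.assembly} "
            f"inconsistent with TOP {top} and relation {loc.strand_relation.value}")


class Registry:
    """In-memory variant registry for one species."""

    def __init__(self, species: str = "sheep"):
        self.species = species
        self._variants: dict[str, Variant] = {}
        self._alias: dict[tuple[str, str], str] = {}  # (chip, alias) -> name
        self._rs: dict[str, str] = {}
        self._pos: dict[tuple[str, str, int], dict[str, str]] = {}
        self.chips: set[str] = set()

    def __len__(self) -> int:
        return len(self._variants)

    def __iter__(self) -> Iterator[Variant]:
        return iter(self._variants.values())

    def __contains__(self, name: str) -> bool:
        return name in self._variants

    # -- mutation ---------------------------------------------------------

    def add_variant(self, variant: Variant) -> Variant:
        """Add or merge a variant; idempotent.

        Re-adding identical information is a no-op.  A second chip's record
        for the same SNP merges its alias, probesets and locations into the
        existing document.  If the new record's TOP alleles disagree with
        the stored ones, both are kept (stored wins, new under
        ``extra['top_conflicts']``) and the variant is flagged
        ``top_conflict`` rather than silently overwritten.
        """
        existing = self._variants.get(variant.name)
        if existing is None:
            self._index(variant)
            self._variants[variant.name] = variant
            return variant
        return self._merge(existing, variant)

    def _index(self, variant: Variant, chips_only: bool = False) -> None:
        for chip, alias in variant.aliases.items():
            bound = self._alias.get((chip, alias))
            if bound is not None and bound != variant.name:
                raise AliasConflictError(
                    f"alias {alias!r} on chip {chip!r} already bound to "
                    f"{bound!r}, cannot bind to {variant.name!r}")
        if chips_only:
            return
        for chip, alias in variant.aliases.items():
            self._alias[(chip, alias)] = variant.name
        self.chips.update(variant.chip_names)
        if variant.rs_id:
            self._rs.setdefault(variant.rs_id, variant.name)
        for loc in variant.locations:
            if loc.is_mapped:
                slot = self._pos.setdefault(
                    (loc.assembly, loc.chromosome, loc.position), {})
                slot.setdefault(loc.source, variant.name)

    def _merge(self, existing: Variant, new: Variant) -> Variant:
        self._index(new, chips_only=True)  # validate aliases before mutating
        if new.illumina_top.as_set != existing.illumina_top.as_set:
            conflicts = existing.extra.setdefault("top_conflicts", [])
            entry = {"top": str(new.illumina_top),
                     "chips": sorted(new.chip_names)}
            if entry not in conflicts:
                conflicts.append(entry)
                existing.flags.add("top_conflict")
                logger.warning("%s: conflicting TOP alleles %s vs stored %s",
                               existing.name, new.illumina_top,
                               existing.illumina_top)
        existing.chip_names |= new.chip_names
        existing.aliases.update(new.aliases)
        for ps in new.probesets:
            if ps not in existing.probesets:
                existing.probesets.append(ps)
        if existing.rs_id is None and new.rs_id:
            existing.rs_id = new.rs_id
        if existing.probe_seq is None and new.probe_seq:
            existing.probe_seq = new.probe_seq
        existing.flags |= new.flags
        for loc in new.locations:
            current = next((l for l in existing.locations if l.key == loc.key), None)
            if current is None:
                _check_forward(existing.name, existing.illumina_top, loc)
                existing.locations.append(loc)
            elif current != loc:
                raise LocationConflictError(
                    f"{existing.name}: location {loc.key} already recorded "
                    f"as {current.chromosome}:{current.position}, refusing "
                    f"{loc.chromosome}:{loc.position}")
        for k, v in new.extra.items():
            existing.extra.setdefault(k, v)
        self._index(existing)
        return existing

    # -- lookup -----------------------------------------------------------

    def get(self, name: str) -> Variant | None:
        """Lookup by canonical name, falling back to rs ID."""
        variant = self._variants.get(name)
        if variant is None and name in self._rs:
            variant = self._variants.get(self._rs[name])
        return variant

    def get_alias(self, chip_name: str, alias: str) -> Variant | None:
        name = self._alias.get((chip_name, alias))
        return self._variants.get(name) if name else None

    def get_position(self, assembly: str, chromosome: str,
                     position: int) -> Variant | None:
        slot = self._pos.get((assembly, str(chromosome), int(position)))
        if not slot:
            return None
        for source in sorted(slot, key=lambda s: (_source_rank(s), s)):
            return self._variants[slot[source]]
        return None

    def resolve(self, name: str, chip_name: str | None = None) -> Variant | None:
        """Canonical-name lookup, then chip alias, then any-chip alias."""
        variant = self.get(name)
        if variant is not None:
            return variant
        if chip_name is not None:
            variant = self.get_alias(chip_name, name)
            if variant is not None:
                return variant
        for (chip, alias), vname in self._alias.items():
            if alias == name:
                return self._variants[vname]
        return None

    def common_snps(self, chip_a: str, chip_b: str) -> set[str]:
        """Canonical names of variants carried by both chips; symmetric."""
        for chip in (chip_a, chip_b):
            if chip not in self.chips:
                raise KeyError(f"unknown chip: {chip!r}")
        return {v.name for v in self
                if chip_a in v.chip_names and chip_b in v.chip_names}

    def stats(self) -> dict:
        assemblies = sorted({l.assembly for v in self for l in v.locations})
        return {
            "species": self.species,
            "n_variants": len(self),
            "chips": sorted(self.chips),
            "assemblies": assemblies,
            "n_flagged": sum(1 for v in self if v.flags),
        }

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        """Write one JSON record per variant (JSON-lines, sorted keys)."""
        path = Path(path)
        with path.open("w") as fh:
            header = {"_type": "registry", "species": self.species,
                      "chips": sorted(self.chips)}
            fh.write(json.dumps(header, sort_keys=True) + "\n")
            for name in sorted(self._variants):
                fh.write(json.dumps(_variant_to_doc(self._variants[name]),
                                    sort_keys=True) + "\n")

    @classmethod
    def load(cls, path) -> "Registry":
        path = Path(path)
        with path.open() as fh:
            header = json.loads(fh.readline())
            if header.get("_type") != "registry":
                raise ValueError(f"{path}: not a registry file")
            reg = cls(species=header["species"])
            reg.chips.update(header.get("chips", []))
            for line in fh:
                if line.strip():
                    reg.add_variant(_variant_from_doc(json.loads(line)))
        return reg


def _variant_to_doc(v: Variant) -> dict:
    return {
        "name": v.name,
        "rs_id": v.rs_id,
        "illumina_top": str(v.illumina_top),
        "chip_names": sorted(v.chip_names),
        "aliases": v.aliases,
        "probe_seq": v.probe_seq,
        "probesets": [list(p) for p in v.probesets],
        "flags": sorted(v.flags),
        "extra": v.extra,
        "locations": [
            {"assembly": l.assembly, "chromosome": l.chromosome,
             "position": l.position,
             "illumina_forward": (str(l.illumina_forward)
                                  if l.illumina_forward else None),
             "strand_relation": l.strand_relation.value,
             "source": l.source}
            for l in v.locations
        ],
    }


def _variant_from_doc(doc: dict) -> Variant:
    return Variant(
        name=doc["name"],
        rs_id=doc.get("rs_id"),
        illumina_top=AllelePair.from_string(doc["illumina_top"]),
        chip_names=set(doc.get("chip_names", [])),
        aliases=dict(doc.get("aliases", {})),
        probe_seq=doc.get("probe_seq"),
        probesets=[tuple(p) for p in doc.get("probesets", [])],
        flags=set(doc.get("flags", [])),
        extra=dict(doc.get("extra", {})),
        locations=[
            Location(
                assembly=l["assembly"], chromosome=l["chromosome"],
                position=l["position"],
                illumina_forward=(AllelePair.from_string(l["illumina_forward"])
                                  if l.get("illumina_forward") else None),
                strand_relation=StrandRelation(l.get("strand_relation", "unknown")),
                source=l.get("source", "illumina"))
            for l in doc.get("locations", [])
        ],
    )
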