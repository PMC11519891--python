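"""Variant registry: lookup identities, idempotent import, remapping."""

import pytest

from snpharmony import (
    AllelePair,
    Coding,
    Location,
    Registry,
    StrandRelation,
    Variant,
    complement,
    make_dataset,
    remap_positions,
)
from snpharmony.errors import AliasConflictError, SnpHarmonyError


def make_variant(name="SNP1", top=("A", "G"), chip="chipX", rs=None,
                 locations=()):
    return Variant(name=name, illumina_top=AllelePair(*top), rs_id=rs,
                   chip_names={chip}, aliases={chip: name},
                   locations=list(locations))


class TestAddAndLookup:
    def test_lookup_by_every_identity_returns_same_object(self):
        reg = Registry("sheep")
        loc = Location(assembly="Oar_v4.0", chromosome="3", position=1234,
                       illumina_forward=AllelePair("A", "G"),
                       strand_relation=StrandRelation.SAME)
        v = make_variant("DU186191_327.1", rs="rs1234", locations=[loc])
        reg.add_variant(v)
        by_name = reg.get("DU186191_327.1")
        assert by_name is reg.get("rs1234")
        assert by_name is reg.get_alias("chipX", "DU186191_327.1")
        assert by_name is reg.get_position("Oar_v4.0", "3", 1234)
        assert by_name.illumina_top == AllelePair("A", "G")

    def test_readding_identical_variant_is_noop(self):
        reg = Registry("sheep")
        reg.add_variant(make_variant())
        reg.add_variant(make_variant())
        assert len(reg) == 1

    def test_alias_collision_with_different_variant_raises(self):
        reg = Registry("sheep")
        v1 = make_variant("SNP1")
        v1.aliases["affy"] = "AX-123"
        v2 = make_variant("SNP2")
        v2.aliases["affy"] = "AX-123"
        reg.add_variant(v1)
        with pytest.raises(AliasConflictError) as err:
            reg.add_variant(v2)
        assert "SNP1" in str(err.value) and "SNP2" in str(err.value)

    def test_second_chip_merges_into_same_document(self):
        reg = Registry("sheep")
        reg.add_variant(make_variant(chip="chip50k"))
        other = make_variant(chip="chipHD")
        other.aliases = {"chipHD": "snp1-hd-name"}
        reg.add_variant(other)
        assert len(reg) == 1
        v = reg.get("SNP1")
        assert v.chip_names == {"chip50k", "chipHD"}
        assert reg.get_alias("chipHD", "snp1-hd-name") is v

    def test_conflicting_top_alleles_flagged_not_overwritten(self):
        reg = Registry("sheep")
        reg.add_variant(make_variant(top=("A", "G"), chip="chipA"))
        reg.add_variant(make_variant(top=("A", "C"), chip="chipB"))
        v = reg.get("SNP1")
        assert v.illumina_top == AllelePair("A", "G")
        assert "top_conflict" in v.flags

    def test_unknown_name_is_not_found_value(self):
        assert Registry("sheep").get("nope") is None

    def test_position_lookup_prefers_illumina_source(self):
        reg = Registry("sheep")
        ilmn = Location(assembly="ARS1.2", chromosome="2", position=500,
                        source="illumina")
        affy = Location(assembly="ARS1.2", chromosome="2", position=500,
                        source="affymetrix")
        reg.add_variant(make_variant("ILMN_SNP", locations=[ilmn]))
        v2 = Variant(name="AFFY_SNP", illumina_top=AllelePair("A", "C"),
                     chip_names={"affy"}, aliases={"affy": "AX-9"},
                     locations=[affy])
        reg.add_variant(v2)
        assert reg.get_position("ARS1.2", "2", 500).name == "ILMN_SNP"


class TestCommonSnps:
    def build(self):
        reg = Registry("goat")
        for i in range(5):
            v = make_variant(f"S{i}", chip="chipA")
            if i < 3:
                v.chip_names.add("chipB")
                v.aliases["chipB"] = f"S{i}"
            reg.add_variant(v)
        return reg

    def test_shared_snps_match_brute_force(self):
        reg = self.build()
        brute = {v.name for v in reg
                 if {"chipA", "chipB"} <= v.chip_names}
        assert reg.common_snps("chipA", "chipB") == brute == {"S0", "S1", "S2"}
        assert reg.common_snps("chipB", "chipA") == brute  # symmetric

    def test_chip_with_itself_gives_all_its_variants(self):
        reg = self.build()
        assert reg.common_snps("chipB", "chipB") == {"S0", "S1", "S2"}

    def test_disjoint_chips_and_unknown_chip(self):
        reg = self.build()
        reg.add_variant(make_variant("X0", chip="chipC"))
        assert reg.common_snps("chipB", "chipC") == set()
        with pytest.raises(KeyError):
            reg.common_snps("chipA", "nope")


class TestInvariants:
    def test_forward_alleles_recoverable_from_relation(self, small_registry):
        for variant in small_registry:
            for loc in variant.locations:
                if loc.strand_relation is StrandRelation.UNKNOWN:
                    continue
                if loc.strand_relation is StrandRelation.SAME:
                    expected = variant.illumina_top.as_set
                else:
                    expected = {complement(b)
                                for b in variant.illumina_top.as_set}
                assert loc.illumina_forward.as_set == expected, variant.name

    def test_save_load_round_trip(self, small_registry, tmp_path):
        path = tmp_path / "registry.jsonl"
        small_registry.save(path)
        loaded = Registry.load(path)
        assert len(loaded) == len(small_registry)
        assert loaded.species == small_registry.species
        for v in small_registry:
            w = loaded.get(v.name)
            assert w.illumina_top == v.illumina_top
            assert w.aliases == v.aliases
            assert {l.key: (l.chromosome, l.position) for l in w.locations} \
                == {l.key: (l.chromosome, l.position) for l in v.locations}

    def test_save_is_deterministic(self, small_registry, tmp_path):
        a, b = tmp_path / "a.jsonl", tmp_path / "b.jsonl"
        small_registry.save(a)
        small_registry.save(b)
        assert a.read_bytes() == b.read_bytes()


class TestRemapPositions:
    def test_remap_rewrites_coordinates_not_genotypes(self, small_registry,
                                                      small_spec):
        ds, truth, _ = make_dataset(small_registry, small_spec)
        assert ds.assembly == "Oar_v4.0"
        remapped = remap_positions(ds, "Oar_v3.1", small_registry)
        assert (remapped.calls == ds.calls).all()
        for snp in remapped.snps:
            loc = small_registry.get(snp.name).location("Oar_v3.1")
            assert (snp.chromosome, snp.position) == \
                (loc.chromosome, loc.position)

    def test_remap_round_trip_restores_coordinates(self, small_registry,
                                                   small_spec):
        ds, _, _ = make_dataset(small_registry, small_spec)
        back = remap_positions(
            remap_positions(ds, "Oar_v3.1", small_registry),
            "Oar_v4.0", small_registry)
        assert [(s.chromosome, s.position) for s in back.snps] == \
            [(s.chromosome, s.position) for s in ds.snps]

    def test_remap_to_current_assembly_is_identity(self, small_registry,
                                                   small_spec):
        ds, _, _ = make_dataset(small_registry, small_spec)
        same = remap_positions(ds, "Oar_v4.0", small_registry)
        assert [(s.chromosome, s.position) for s in same.snps] == \
            [(s.chromosome, s.position) for s in ds.snps]

    def test_snp_absent_from_target_becomes_unmapped(self, small_spec):
        registry, _ = __import__("snpharmony").make_registry(small_spec)
        ds, _, _ = make_dataset(registry, small_spec)
        orphan = registry.get(ds.snps[5].name)
        orphan.locations = [l for l in orphan.locations
                            if l.assembly != "Oar_v3.1"]
        remapped = remap_positions(ds, "Oar_v3.1", registry)
        assert remapped.snps[5].chromosome == "0"
        assert remapped.snps[5].position == 0

    def test_refuses_non_top_coding(self, small_registry, small_spec):
        from dataclasses import replace

        spec = replace(small_spec, coding=Coding.ILLUMINA_AB)
        ds, _, _ = make_dataset(small_registry, spec)
        with pytest.raises(SnpHarmonyError):
            remap_positions(ds, "Oar_v3.1", small_registry)
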