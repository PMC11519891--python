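"""Stable ID assignment, SNP-union merging and IBS duplicate detection."""

from dataclasses import replace

import numpy as np
import pytest

from snpharmony import (
    Coding,
    FixtureSpec,
    GenotypeDataset,
    IdState,
    SampleInfo,
    SmarterId,
    SnpInfo,
    assign_smarter_ids,
    compute_ibs,
    drop_samples,
    find_duplicates,
    make_dataset,
    make_registry,
    merge_datasets,
)
from snpharmony.errors import MergeConflictError, SnpHarmonyError


class TestSmarterIds:
    def test_rendering_matches_published_exemplars(self):
        assert str(SmarterId("UY", "OA", "CRR", 3890)) == "UYOA-CRR-000003890"
        assert str(SmarterId("GR", "OA", "CHI", 4137)) == "GROA-CHI-000004137"

    def test_parse_round_trip(self):
        sid = SmarterId.parse("UYOA-CRR-000003890")
        assert (sid.country, sid.species, sid.breed_code, sid.counter) == \
            ("UY", "OA", "CRR", 3890)

    def test_malformed_rejected(self):
        with pytest.raises(ValueError):
            SmarterId.parse("UYOA-CRR-1")
        with pytest.raises(ValueError):
            SmarterId("Uruguay", "OA", "CRR", 1)

    def rows(self):
        return [{"dataset": "ds1", "original_id": f"orig{i}",
                 "country": "UY", "breed_code": "CRR"} for i in range(3)]

    def test_assignment_is_sequential_and_species_scoped(self):
        ids, state = assign_smarter_ids(self.rows(), "sheep")
        assert [str(s) for s in ids] == [
            "UYOA-CRR-000000001", "UYOA-CRR-000000002", "UYOA-CRR-000000003"]
        goat_ids, _ = assign_smarter_ids(
            [{"dataset": "g", "original_id": "x", "country": "GR",
              "breed_code": "CHI"}], "goat")
        assert str(goat_ids[0]) == "GRCH-CHI-000000001"

    def test_replay_is_idempotent(self):
        ids1, state = assign_smarter_ids(self.rows(), "sheep")
        ids2, state = assign_smarter_ids(self.rows(), "sheep", state)
        assert ids1 == ids2
        assert state.counter == 3  # counter not advanced on replay

    def test_new_samples_continue_counter(self):
        _, state = assign_smarter_ids(self.rows(), "sheep")
        more = [{"dataset": "ds2", "original_id": "orig0", "country": "GR",
                 "breed_code": "CHI"}]
        ids, state = assign_smarter_ids(more, "sheep", state)
        assert str(ids[0]) == "GROA-CHI-000000004"

    def test_missing_country_or_breed_lists_offenders(self):
        rows = self.rows()
        rows[1]["country"] = ""
        with pytest.raises(SnpHarmonyError, match="orig1"):
            assign_smarter_ids(rows, "sheep")

    def test_state_round_trip(self, tmp_path):
        _, state = assign_smarter_ids(self.rows(), "sheep")
        state.save(tmp_path / "state.json")
        loaded = IdState.load(tmp_path / "state.json")
        assert loaded == state


def subset(dataset, snp_names, sample_slice, source):
    idx = dataset.snp_index()
    cols = [idx[n] for n in snp_names]
    rows = list(range(*sample_slice.indices(dataset.n_samples)))
    return GenotypeDataset(
        samples=[dataset.samples[i] for i in rows],
        snps=[dataset.snps[c] for c in cols],
        calls=dataset.calls[np.ix_(rows, cols)],
        coding=dataset.coding, assembly=dataset.assembly,
        chip_name=dataset.chip_name, source=source)


class TestMerge:
    @pytest.fixture()
    def top_fixture(self, small_registry, small_spec):
        ds, truth, _ = make_dataset(small_registry, small_spec)
        return ds

    def test_union_and_missing_fill_match_brute_force(self, small_registry,
                                                      top_fixture):
        names = [s.name for s in top_fixture.snps]
        a = subset(top_fixture, names[:5], slice(0, 4), "dsA")
        b = subset(top_fixture, names[2:6], slice(4, 8), "dsB")
        merged = merge_datasets([a, b], small_registry)
        assert merged.n_snps == len(set(names[:5]) | set(names[2:6])) == 6
        assert merged.n_samples == 8
        # brute-force oracle: every source call lands at its cell, all else missing
        col = merged.snp_index()
        for src in (a, b):
            for i, sample in enumerate(src.samples):
                gi = [s.key for s in merged.samples].index(sample.key)
                for j, snp in enumerate(src.snps):
                    assert merged.calls[gi, col[snp.name]] == src.calls[i, j]
        on_chip = {s.key: set(n for n in names[:5]) for s in a.samples}
        on_chip.update({s.key: set(names[2:6]) for s in b.samples})
        for gi, sample in enumerate(merged.samples):
            for name, gj in col.items():
                if name not in on_chip[sample.key]:
                    assert merged.calls[gi, gj] == "00"

    def test_merged_missing_count_identity(self, small_registry, top_fixture):
        names = [s.name for s in top_fixture.snps]
        a = subset(top_fixture, names[:5], slice(0, 4), "dsA")
        b = subset(top_fixture, names[2:6], slice(4, 8), "dsB")
        merged = merge_datasets([a, b], small_registry)
        expected = (a.missing_mask().sum() + b.missing_mask().sum()
                    + a.n_samples * (merged.n_snps - a.n_snps)
                    + b.n_samples * (merged.n_snps - b.n_snps))
        assert merged.missing_mask().sum() == expected

    def test_single_dataset_merge_reorders_by_position(self, small_registry,
                                                       top_fixture):
        merged = merge_datasets([top_fixture], small_registry)
        assert merged.n_snps == top_fixture.n_snps
        keys = [( s.chromosome == "0",
                  int(s.chromosome) if s.chromosome.isdigit() else 0,
                  s.position) for s in merged.snps]
        assert keys == sorted(keys)
        assert sorted(s.name for s in merged.snps) == \
            sorted(s.name for s in top_fixture.snps)

    def test_disjoint_merge_gives_m_plus_n(self, small_registry, top_fixture):
        names = [s.name for s in top_fixture.snps]
        a = subset(top_fixture, names[:4], slice(0, 3), "dsA")
        b = subset(top_fixture, names[4:9], slice(3, 6), "dsB")
        merged = merge_datasets([a, b], small_registry)
        assert merged.n_snps == 9
        for i in range(3):  # dsA samples missing on dsB SNPs
            for name in names[4:9]:
                assert merged.calls[i, merged.snp_index()[name]] == "00"

    def test_alias_unification(self, small_registry, top_fixture):
        names = [s.name for s in top_fixture.snps]
        a = subset(top_fixture, names[:3], slice(0, 2), "dsA")
        b = subset(top_fixture, names[:3], slice(2, 4), "dsB")
        b.chip_name = "otherchip"
        renamed = []
        for snp in b.snps:
            variant = small_registry.get(snp.name)
            variant.chip_names.add("otherchip")
            variant.aliases["otherchip"] = f"alias-{snp.name}"
            small_registry.add_variant(variant)
            renamed.append(replace(snp, name=f"alias-{snp.name}"))
        b.snps = renamed
        merged = merge_datasets([a, b], small_registry)
        assert merged.n_snps == 3  # aliases resolved to canonical names
        assert all(not s.name.startswith("alias-") for s in merged.snps)

    def test_conflicting_top_alleles_raise(self, small_registry, top_fixture):
        names = [s.name for s in top_fixture.snps]
        a = subset(top_fixture, names[:3], slice(0, 2), "dsA")
        bad = a.copy()
        bad.snps = [replace(bad.snps[0], allele1="C", allele2="G")] + \
            bad.snps[1:]
        bad.calls[:, 0] = "CC"
        with pytest.raises(MergeConflictError, match=names[0]):
            merge_datasets([a, bad], small_registry)

    def test_non_top_coding_refused(self, small_registry, small_spec):
        spec = replace(small_spec, coding=Coding.ILLUMINA_AB)
        ds, _, _ = make_dataset(small_registry, spec)
        with pytest.raises(SnpHarmonyError, match="TOP"):
            merge_datasets([ds], small_registry)


class TestIbs:
    def test_definitional_values(self):
        assert compute_ibs(["AA"], ["AG"]) == 0.5
        assert compute_ibs(["AA", "AG"], ["GG", "AG"]) == 0.5  # mean(0, 1)
        assert compute_ibs(["AG"], ["GA"]) == 1.0  # order-insensitive
        assert compute_ibs(["AA", "00"], ["AA", "GG"]) == 1.0  # joint loci only
        assert compute_ibs(["00"], ["AA"]) is None  # no comparison

    def test_symmetry_and_self_identity(self):
        a = ["AA", "AG", "GG", "00", "AG"]
        b = ["AG", "AA", "GG", "AA", "00"]
        assert compute_ibs(a, b) == compute_ibs(b, a)
        assert compute_ibs(a, a) == 1.0

    def test_locus_order_invariance(self):
        a = ["AA", "AG", "GG"]
        b = ["AG", "GG", "GG"]
        assert compute_ibs(a, b) == compute_ibs(a[::-1], b[::-1])

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            compute_ibs(["AA"], ["AA", "GG"])


class TestFindDuplicates:
    def make(self, seed, n_duplicates=2, n_snps=300):
        spec = FixtureSpec(n_snps=n_snps, n_samples=10, seed=seed,
                           n_duplicates=n_duplicates)
        registry, _ = make_registry(spec)
        ds, truth, _ = make_dataset(registry, spec)
        return ds, truth

    def test_planted_duplicates_flagged_no_false_positives(self):
        for seed in range(3):
            ds, truth = self.make(seed)
            report = find_duplicates(ds, threshold=0.95)
            flagged = {frozenset((f.sample_a, f.sample_b))
                       for f in report.flagged}
            planted = {frozenset(p) for p in truth.duplicate_pairs}
            assert flagged == planted, seed

    def test_survivor_has_fewer_missing_calls(self):
        ds, truth = self.make(1)
        report = find_duplicates(ds, threshold=0.95)
        missing = dict(zip([s.key for s in ds.samples],
                           ds.n_missing_per_sample()))
        for fp in report.flagged:
            assert missing[fp.survivor] <= missing[fp.removed]

    def test_threshold_one_with_exact_copies_only(self):
        spec = FixtureSpec(n_snps=100, n_samples=6, seed=5, n_duplicates=2,
                           duplicate_missing_rate=0.0, missing_rate=0.0)
        registry, _ = make_registry(spec)
        ds, truth, _ = make_dataset(registry, spec)
        report = find_duplicates(ds, threshold=1.0)
        flagged = {frozenset((f.sample_a, f.sample_b))
                   for f in report.flagged}
        assert flagged == {frozenset(p) for p in truth.duplicate_pairs}

    def test_between_mode_skips_within_dataset_pairs(self):
        ds, truth = self.make(2)
        ds.sample_origins = ["one"] * ds.n_samples
        report = find_duplicates(ds, threshold=0.95, mode="between")
        assert report.pairs == [] and report.flagged == []

    def test_drop_samples_applies_removal_list(self):
        ds, truth = self.make(3)
        report = find_duplicates(ds, threshold=0.95)
        cleaned = drop_samples(ds, report.removal_list)
        assert cleaned.n_samples == ds.n_samples - len(report.removal_list)
        again = find_duplicates(cleaned, threshold=0.95)
        assert again.flagged == []

    def test_report_tsv_written(self, tmp_path):
        ds, _ = self.make(4, n_duplicates=1, n_snps=100)
        report = find_duplicates(ds, threshold=0.95)
        report.write_tsv(tmp_path / "ibs.tsv")
        lines = (tmp_path / "ibs.tsv").read_text().splitlines()
        assert lines[0].split("\t") == ["sampleA", "sampleB", "ibs",
                                        "n_loci", "flagged", "survivor"]
        assert sum("\tyes\t" in l for l in lines) == len(report.flagged)
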