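"""Variant application rules and post-expansion peptide accounting."""

import pytest

from conftest import oracle_digest
from peptidespace.digestion import DigestionConfig, digest_collection, digest_sequence
from peptidespace.sequence_io import (
    ProteinRecord,
    Section,
    VariantCategory,
    VariantRecord,
)
from peptidespace.variant_expansion import (
    ExpandedRecord,
    coincident_peptide_report,
    expand_variants,
)


def rec(acc, seq, section=Section.reviewed):
    return ProteinRecord(acc, section, "", seq)


def var(entry, feature, pos, ref, alt, category=VariantCategory.polymorphism):
    return VariantRecord(entry, feature, pos, ref, alt, category)


class TestExpandVariants:
    def test_substitution_applied_with_composite_accession(self):
        records = [rec("P1", "ACDEFGHIK")]
        out, log = expand_variants(records, [var("P1", "VAR_0001", 3, "D", "N")])
        assert out[:1] == records  # originals retained
        (new,) = [r for r in out if isinstance(r, ExpandedRecord)]
        assert new.accession == "P1|VAR_0001"
        assert new.sequence == "ACNEFGHIK"
        assert new.source_accession == "P1"
        assert new.entry_accession == "P1"
        assert log.counts() == {"applied_canonical": 1}

    def test_ref_mismatch_is_skipped_and_logged(self):
        out, log = expand_variants(
            [rec("P1", "ACDEFGHIK")], [var("P1", "VAR_0001", 9, "E", "K")]
        )
        assert len(out) == 1
        (event,) = log.skipped
        assert event.reason == "ref_mismatch"

    def test_position_out_of_range_is_skipped(self):
        out, log = expand_variants(
            [rec("P1", "ACDEFGHIK")], [var("P1", "VAR_0001", 100, "A", "G")]
        )
        assert len(out) == 1
        assert log.skipped[0].reason == "position_out_of_range"

    def test_disease_only_mode_filters_categories(self):
        records = [rec("P1", "ACDEFGHIK")]
        variants = [
            var("P1", "VAR_1", 3, "D", "N", VariantCategory.disease),
            var("P1", "VAR_2", 4, "E", "Q", VariantCategory.polymorphism),
        ]
        out_all, _ = expand_variants(records, variants, mode="all")
        out_disease, _ = expand_variants(records, variants, mode="disease_only")
        assert {r.accession for r in out_disease} == {"P1", "P1|VAR_1"}
        # disease_only output is a subset of the all-variants output
        assert {r.accession for r in out_disease} <= {r.accession for r in out_all}

    def test_applies_to_canonical_and_matching_isoform(self):
        # isoform keeps the variant position verbatim -> applied to both
        records = [rec("P1", "ACDEFGHIKAAAAA"), rec("P1-2", "ACDEFGHIK")]
        _, log = expand_variants(records, [var("P1", "VAR_1", 3, "D", "N")])
        assert log.counts() == {"applied_canonical": 1, "applied_isoform": 1}

    def test_isoform_with_shifted_coordinates_is_skipped(self):
        # deletion upstream of the site shifts the residue -> verbatim check fails
        records = [rec("P1", "AACDDDEFGHIK"), rec("P1-2", "ACDDDEFGHIK")]
        _, log = expand_variants(records, [var("P1", "VAR_1", 7, "E", "Q")])
        assert log.counts() == {"applied_canonical": 1, "skipped_ref_mismatch": 1}

    def test_expanded_sequence_differs_at_exactly_one_position(self, synthetic_dataset):
        ds = synthetic_dataset
        out, _ = expand_variants(ds.records, ds.variants)
        by_acc = {r.accession: r for r in ds.records}
        expanded = [r for r in out if isinstance(r, ExpandedRecord)]
        assert expanded
        for e in expanded:
            src = by_acc[e.source_accession]
            assert len(e.sequence) == len(src.sequence)
            diffs = [
                i for i, (a, b) in enumerate(zip(e.sequence, src.sequence)) if a != b
            ]
            assert len(diffs) == 1


class TestPeptideAccounting:
    def test_expansion_digest_is_a_peptide_superset(self, synthetic_dataset):
        ds = synthetic_dataset
        expanded, _ = expand_variants(ds.records, ds.variants)
        base = digest_collection(ds.records, ds.config.digestion)
        exp = digest_collection(expanded, ds.config.digestion)
        assert base.peptides <= exp.peptides

    def test_changed_peptides_match_brute_force_redigestion(self, synthetic_dataset):
        """Per-variant changed peptide sets agree with an independent oracle."""
        ds = synthetic_dataset
        config = ds.config.digestion
        expanded, _ = expand_variants(ds.records, ds.variants)
        by_acc = {r.accession: r for r in ds.records}
        for e in [r for r in expanded if isinstance(r, ExpandedRecord)][:100]:
            src_seq = by_acc[e.source_accession].sequence
            got_changed = {p for p, _ in digest_sequence(e.sequence, config)} ^ {
                p for p, _ in digest_sequence(src_seq, config)
            }
            want_changed = {p for p, _ in oracle_digest(e.sequence)} ^ {
                p for p, _ in oracle_digest(src_seq)
            }
            assert got_changed == want_changed

    def test_variant_without_new_cleavage_changes_few_peptides(self):
        # m=0 and no K/R/P involved: at most the covering peptide changes
        records = [rec("P1", "AAADDDKCCCEEEKGGGFFFK")]
        variants = [var("P1", "VAR_1", 9, "C", "W")]
        expanded, _ = expand_variants(records, variants)
        config = DigestionConfig(min_length=1)
        base = {p for p, _ in digest_sequence(records[0].sequence, config)}
        new = {
            p for p, _ in digest_sequence(expanded[-1].sequence, config)
        }
        assert new - base == {"CWCEEEK"}
        assert base - new == {"CCCEEEK"}

    def test_coincident_report_counts_all_three_classes(self):
        base_records = [rec("P1", "AAADDDKCCCEEEK")]
        variants = [var("P1", "VAR_1", 9, "C", "W")]
        expanded, _ = expand_variants(base_records, variants)
        config = DigestionConfig(min_length=6)
        base_idx = digest_collection(base_records, config)
        exp_idx = digest_collection(expanded, config)
        # other DB happens to contain the variant peptide
        other_idx = digest_collection([rec("X1", "CWCEEEKAAAAAA")], config)
        report = coincident_peptide_report(base_idx, exp_idx, other_idx)
        assert report.additional_peptides == {"CWCEEEK"}
        assert report.coincident_with_other == {"CWCEEEK"}
        # the unchanged peptide of the variant record coincides with the base
        assert report.coincident_within_base == {"AAADDDK"}

    def test_no_variants_means_no_additional_peptides(self, simple_records):
        config = DigestionConfig()
        expanded, _ = expand_variants(simple_records, [])
        base_idx = digest_collection(simple_records, config)
        exp_idx = digest_collection(expanded, config)
        report = coincident_peptide_report(base_idx, exp_idx)
        assert report.n_additional == 0
        assert report.coincident_with_other == frozenset()
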