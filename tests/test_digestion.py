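"""Tryptic digestion against hand-derived examples and independent oracles."""

import random

import pytest
from hypothesis import given, settings, strategies as st
from pyteomics import parser as pyt_parser

from conftest import oracle_digest, random_protein_sequence
from peptidespace.digestion import (
    CleavageRule,
    DigestionConfig,
    Peptide,
    digest_collection,
    digest_sequence,
    mono_mass,
)
from peptidespace.sequence_io import ProteinRecord, Section

WATER = 18.010565


class TestDigestSequence:
    def test_cleaves_after_k_and_r(self):
        assert digest_sequence("AAAAAKCCCCCCR") == [("AAAAAK", 0), ("CCCCCCR", 6)]

    def test_proline_blocks_cleavage(self):
        assert digest_sequence("AAAAAKPCCCCCR") == [("AAAAAKPCCCCCR", 0)]

    def test_trypsin_p_ignores_proline(self):
        config = DigestionConfig(rule=CleavageRule.trypsin_p)
        assert digest_sequence("AAAAAKPCCCCCR", config) == [
            ("AAAAAK", 0),
            ("PCCCCCR", 6),
        ]

    def test_short_fragments_filtered(self):
        assert digest_sequence("ACKDEK") == []

    def test_initiator_methionine_not_trimmed(self):
        assert digest_sequence("MAAAAAKCCCCCCR") == [("MAAAAAK", 0), ("CCCCCCR", 7)]

    def test_ambiguity_codes_never_cleave(self):
        # B may denote N/D but is not a literal K/R: no cleavage at B
        assert digest_sequence("AAABAAKCCCCCCR") == [("AAABAAK", 0), ("CCCCCCR", 7)]

    def test_missed_cleavages_concatenate_consecutive_fragments(self):
        config = DigestionConfig(missed_cleavages=1)
        assert digest_sequence("AAAAAKCCCCCCR", config) == [
            ("AAAAAK", 0),
            ("AAAAAKCCCCCCR", 0),
            ("CCCCCCR", 6),
        ]

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            digest_sequence("")

    @pytest.mark.parametrize("rule", ["trypsin", "trypsin_p"])
    @pytest.mark.parametrize("missed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, rng, rule, missed):
        config = DigestionConfig(rule=CleavageRule(rule), missed_cleavages=missed)
        for _ in range(300):
            seq = random_protein_sequence(rng)
            got = set(digest_sequence(seq, config))
            want = oracle_digest(seq, rule, missed, min_length=6)
            assert got == want, seq

    def test_matches_pyteomics_icleave(self, rng):
        # independent machinery: pyteomics regex cleavage with the same rule
        regexes = {"trypsin": r"[KR](?!P)", "trypsin_p": r"[KR]"}
        for rule, regex in regexes.items():
            for missed in (0, 1, 2):
                config = DigestionConfig(
                    rule=CleavageRule(rule), missed_cleavages=missed, min_length=1
                )
                for _ in range(50):
                    seq = random_protein_sequence(rng, max_len=100)
                    got = {(p, s) for p, s in digest_sequence(seq, config)}
                    want = {
                        (pep, start)
                        for start, pep in pyt_parser.icleave(
                            seq, regex, missed_cleavages=missed
                        )
                    }
                    assert got == want


@settings(max_examples=200, derandomize=True)
@given(seq=st.text(alphabet="ACDEFGHIKLMNPQRSTVWYKRP", min_size=1, max_size=120))
def test_partition_property(seq):
    """m=0, min_length=1 peptides are disjoint and concatenate to the input."""
    config = DigestionConfig(min_length=1)
    peps = digest_sequence(seq, config)
    assert "".join(p for p, _ in peps) == seq
    pos = 0
    for pep, offset in peps:
        assert offset == pos
        pos += len(pep)


@settings(max_examples=100, derandomize=True)
@given(
    seq=st.text(alphabet="ACDEFGHIKLMNPQRSTVWYKRP", min_size=1, max_size=120),
    lo=st.integers(1, 8),
    hi=st.integers(1, 8),
)
def test_raising_min_length_never_adds_peptides(seq, lo, hi):
    lo, hi = min(lo, hi), max(lo, hi)
    small = set(digest_sequence(seq, DigestionConfig(min_length=lo)))
    big = set(digest_sequence(seq, DigestionConfig(min_length=hi)))
    assert big <= small


@settings(max_examples=100, derandomize=True)
@given(seq=st.text(alphabet="ACDEFGHIKLMNPQRSTVWYKRP", min_size=1, max_size=120))
def test_trypsin_peptides_are_concatenations_of_trypsin_p_fragments(seq):
    trypsin = digest_sequence(seq, DigestionConfig(min_length=1))
    tp_sites = {off for _, off in digest_sequence(
        seq, DigestionConfig(rule=CleavageRule.trypsin_p, min_length=1))}
    for pep, off in trypsin:
        # every trypsin peptide starts on a trypsin/P boundary and is a
        # concatenation of consecutive trypsin/P fragments
        assert off in tp_sites
        assert off + len(pep) == len(seq) or off + len(pep) in tp_sites


class TestMonoMass:
    def test_hexaglycine_against_residue_table(self):
        # 6 x 57.02146 + water, computed from a published residue-mass table
        assert mono_mass("GGGGGG") == pytest.approx(360.1393, abs=1e-4)

    def test_ambiguous_peptides_are_indeterminate(self):
        assert mono_mass("GX") is None
        assert mono_mass("GB") is None
        assert mono_mass("GZ") is None

    def test_selenocysteine_has_a_mass(self):
        assert mono_mass("GU") == pytest.approx(
            57.02146 + 150.953636 + WATER, abs=1e-3
        )

    @settings(max_examples=100, derandomize=True)
    @given(
        p1=st.text(alphabet="ACDEFGHIKLMNPQRSTVWYU", min_size=1, max_size=30),
        p2=st.text(alphabet="ACDEFGHIKLMNPQRSTVWYU", min_size=1, max_size=30),
    )
    def test_additivity(self, p1, p2):
        assert mono_mass(p1 + p2) == pytest.approx(
            mono_mass(p1) + mono_mass(p2) - WATER, abs=1e-6
        )

    def test_empty_peptide_errors(self):
        with pytest.raises(ValueError):
            mono_mass("")

    def test_peptide_type_derives_fields(self):
        p = Peptide.from_sequence("AXAAAK")
        assert p.length == 6 and p.is_ambiguous and p.mono_mass is None


class TestDigestCollection:
    def test_occurrences_recorded_across_identical_sequences(self):
        records = [
            ProteinRecord("A1", Section.reviewed, "", "AAAAAKCCCCCCR"),
            ProteinRecord("A2", Section.reviewed, "", "AAAAAKCCCCCCR"),
        ]
        index = digest_collection(records)
        assert index.accessions_of("AAAAAK") == {"A1", "A2"}
        assert index.accessions_of("CCCCCCR") == {"A1", "A2"}

    def test_repeated_peptide_within_one_sequence_keeps_both_offsets(self):
        records = [ProteinRecord("Q1", Section.reviewed, "", "LTMMGTRLTMMGTR")]
        index = digest_collection(records)
        assert {o.offset for o in index.occurrences["LTMMGTR"]} == {0, 7}

    def test_empty_collection_errors(self):
        with pytest.raises(ValueError):
            digest_collection([])

    def test_occurrence_substrings_match(self, synthetic_dataset):
        ds = synthetic_dataset
        by_acc = {r.accession: r.sequence for r in ds.records}
        index = digest_collection(ds.records, ds.config.digestion)
        for pep, occs in list(index.occurrences.items())[:500]:
            for o in occs:
                assert by_acc[o.accession][o.offset : o.offset + len(pep)] == pep
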