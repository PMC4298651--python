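"""Pairwise comparison of two digested collections into three compartments.

The tryptic peptides of two collections DB1 and DB2 split into compartment
I (unique to DB1), II (shared), and III (unique to DB2). Comparing the
accessions behind the compartments identifies the DB1 accessions with no
sequence representative in DB2 (those contributing at least one
compartment-I peptide), and symmetrically. Each compartment can then be
annotated with the count and percentage of peptides that have evidence in
MS proteomics repositories.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence, Union

from peptidespace.digestion import DigestIndex
from peptidespace.repository_evidence import EvidenceSet


class ConfigMismatchError(ValueError):
    """Refuses to compare digests produced under different digestion rules."""


@dataclass(frozen=True)
class ComparisonResult:
    compartment_i: frozenset[str]  # unique to DB1
    compartment_ii: frozenset[str]  # shared
    compartment_iii: frozenset[str]  # unique to DB2
    db1_unrepresented_accessions: frozenset[str]
    db2_unrepresented_accessions: frozenset[str]


def compare(index1: DigestIndex, index2: DigestIndex) -> ComparisonResult:
    """Split peptides of two digests into the three comparison compartments.

    Both indexes must have been built with the same :class:`DigestionConfig`.
    """
    if index1.config != index2.config:
        raise ConfigMismatchError(
            f"digestion configs differ: {index1.config} vs {index2.config}"
        )
    p1, p2 = index1.peptides, index2.peptides
    comp_i = p1 - p2
    comp_iii = p2 - p1
    db1_unrep = frozenset(
        acc for pep in comp_i for acc in index1.accessions_of(pep)
    )
    db2_unrep = frozenset(
        acc for pep in comp_iii for acc in index2.accessions_of(pep)
    )
    return ComparisonResult(
        compartment_i=frozenset(comp_i),
        compartment_ii=frozenset(p1 & p2),
        compartment_iii=frozenset(comp_iii),
        db1_unrepresented_accessions=db1_unrep,
        db2_unrepresented_accessions=db2_unrep,
    )


def format_percent(n_matched: int, n_total: int) -> str:
    """Evidence-percentage formatting: exact zero prints '0', else 1 decimal."""
    if n_matched == 0:
        return "0"
    return f"{100.0 * n_matched / n_total:.1f}"


@dataclass(frozen=True)
class CompartmentEvidence:
    n_peptides: int
    n_with_evidence: int

    @property
    def percent(self) -> float:
        return 100.0 * self.n_with_evidence / self.n_peptides if self.n_peptides else 0.0

    @property
    def percent_str(self) -> str:
        return format_percent(self.n_with_evidence, self.n_peptides)


@dataclass(frozen=True)
class EvidenceAnnotation:
    compartments: Mapping[str, CompartmentEvidence]  # keys: I, II, III


def annotate_with_evidence(
    result: ComparisonResult, evidence: EvidenceSet
) -> EvidenceAnnotation:
    """Per-compartment evidence counts and percentages.

    *evidence* should already be filtered/merged (e.g. PRIDE at >=5
    experiments merged with PeptideAtlas and GPMDB); presence means
    membership in at least one repository of the merged set.
    """
    ev = evidence.peptides

    def _one(peps: frozenset[str]) -> CompartmentEvidence:
        return CompartmentEvidence(n_peptides=len(peps), n_with_evidence=len(peps & ev))

    return EvidenceAnnotation(
        compartments={
            "I": _one(result.compartment_i),
            "II": _one(result.compartment_ii),
            "III": _one(result.compartment_iii),
        }
    )


def write_comparison_tsv(
    result: ComparisonResult,
    annotation: EvidenceAnnotation,
    path: Union[str, Path],
    db1_name: str = "DB1",
    db2_name: str = "DB2",
    header_lines: Sequence[str] = (),
) -> None:
    """One comparison block: DB1-unique, DB2-unique, Common rows."""
    rows = [
        (db1_name, annotation.compartments["I"]),
        (db2_name, annotation.compartments["III"]),
        ("Com.", annotation.compartments["II"]),
    ]
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("dataset\tpeptides\tevidence_count\tevidence_percent\n")
        for name, ce in rows:
            fh.write(
                f"{name}\t{ce.n_peptides}\t{ce.n_with_evidence}\t{ce.percent_str}\n"
            )
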