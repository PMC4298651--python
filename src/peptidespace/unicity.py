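"""Peptide unicity within a collection, at sequence and entry level.

A peptide is sequence-unique when every one of its occurrences lies in a
single sequence (accession); multiple occurrences within that one sequence
still count as unique — the peptide maps unambiguously to one protein.
Entry-level analysis additionally reports peptides shared only among
isoforms (canonical included) of a single entry; those "adjunctive" unique
peptides are kept out of the headline unicity percentage and reported
separately.

Peptides containing the ambiguity codes X, B or Z cannot be matched to
spectra unambiguously and are excludable from the unique counts (they stay
in the totals); U (selenocysteine) peptides are regular peptides and are
never excluded.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Tuple, Union

from peptidespace.digestion import DigestIndex, is_ambiguous
from peptidespace.sequence_io import ProteinRecord, Section, entry_accession_of


@dataclass
class UnicityReport:
    total_peptides: int
    unique_peptides: int
    per_accession_unique_counts: dict[str, int]
    isoform_specific_unique: int
    entry_level_additional_unique: int
    excluded_ambiguous: int
    unique_peptide_set: frozenset[str]
    entry_level_additional_set: frozenset[str]
    #: (peptide, accession, within-sequence occurrence count) with most repeats
    most_repeated_unique: Optional[Tuple[str, str, int]] = None

    @property
    def unicity_percent(self) -> float:
        if self.total_peptides == 0:
            return 0.0
        return 100.0 * self.unique_peptides / self.total_peptides

    @property
    def unicity_percent_str(self) -> str:
        return f"{self.unicity_percent:.1f}"


def unicity_report(
    index: DigestIndex,
    records: Sequence[ProteinRecord],
    exclude_ambiguous: bool = True,
    entry_level: bool = False,
    max_length: Optional[int] = None,
) -> UnicityReport:
    """Evaluate peptide unicity of a digested collection.

    ``max_length`` restricts the peptide universe before any counting
    (e.g. 66 residues, the repository length ceiling). With
    ``exclude_ambiguous`` X/B/Z peptides stay in the totals but are not
    counted unique; the number so excluded is reported.
    """
    by_acc = {r.accession: r for r in records}
    total = 0
    unique = 0
    excluded = 0
    iso_unique = 0
    entry_additional: set[str] = set()
    per_acc: Counter[str] = Counter()
    unique_set: set[str] = set()
    most_repeated: Optional[Tuple[str, str, int]] = None

    for pep, occs in index.occurrences.items():
        if max_length is not None and len(pep) > max_length:
            continue
        total += 1
        accessions = {o.accession for o in occs}
        ambiguous = is_ambiguous(pep)
        if len(accessions) == 1:
            if exclude_ambiguous and ambiguous:
                excluded += 1
                continue
            acc = next(iter(accessions))
            unique += 1
            unique_set.add(pep)
            per_acc[acc] += 1
            rec = by_acc.get(acc)
            if rec is not None and rec.is_isoform:
                iso_unique += 1
            if len(occs) > 1 and (most_repeated is None or len(occs) > most_repeated[2]):
                most_repeated = (pep, acc, len(occs))
        elif entry_level:
            entries = {entry_accession_of(a) for a in accessions}
            if len(entries) == 1 and not (exclude_ambiguous and ambiguous):
                entry_additional.add(pep)

    return UnicityReport(
        total_peptides=total,
        unique_peptides=unique,
        per_accession_unique_counts=dict(per_acc),
        isoform_specific_unique=iso_unique,
        entry_level_additional_unique=len(entry_additional),
        excluded_ambiguous=excluded,
        unique_peptide_set=frozenset(unique_set),
        entry_level_additional_set=frozenset(entry_additional),
        most_repeated_unique=most_repeated,
    )


@dataclass(frozen=True)
class EntrySummary:
    n_accessions_with_unique: int
    by_section: Mapping[str, int]
    n_isoform_accessions: int
    n_canonical_accessions: int
    max_unique_accession: Optional[Tuple[str, int]]
    most_repeated_unique: Optional[Tuple[str, str, int]]


def entries_with_unique_peptides(
    report: UnicityReport, records: Sequence[ProteinRecord]
) -> EntrySummary:
    """Accessions carrying at least one sequence-unique peptide, by class."""
    by_acc = {r.accession: r for r in records}
    by_section: Counter[str] = Counter()
    n_iso = 0
    for acc in report.per_accession_unique_counts:
        rec = by_acc.get(acc)
        if rec is None:
            continue
        by_section[rec.section.value] += 1
        if rec.is_isoform:
            n_iso += 1
    n_with = len(report.per_accession_unique_counts)
    max_acc = (
        max(report.per_accession_unique_counts.items(), key=lambda kv: (kv[1], kv[0]))
        if report.per_accession_unique_counts
        else None
    )
    return EntrySummary(
        n_accessions_with_unique=n_with,
        by_section=dict(by_section),
        n_isoform_accessions=n_iso,
        n_canonical_accessions=n_with - n_iso,
        max_unique_accession=max_acc,
        most_repeated_unique=report.most_repeated_unique,
    )


def write_unicity_tsv(
    report: UnicityReport,
    path: Union[str, Path],
    dataset_name: str = "dataset",
    header_lines: Sequence[str] = (),
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(
            "dataset\ttotal_peptides\tunique_peptides\tunicity_percent\t"
            "isoform_specific_unique\tentry_level_additional_unique\t"
            "excluded_ambiguous\n"
        )
        fh.write(
            f"{dataset_name}\t{report.total_peptides}\t{report.unique_peptides}\t"
            f"{report.unicity_percent_str}\t{report.isoform_specific_unique}\t"
            f"{report.entry_level_additional_unique}\t{report.excluded_ambiguous}\n"
        )


def write_per_accession_tsv(
    report: UnicityReport, path: Union[str, Path], header_lines: Sequence[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("accession\tn_unique_peptides\n")
        for acc in sorted(report.per_accession_unique_counts):
            fh.write(f"{acc}\t{report.per_accession_unique_counts[acc]}\n")
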