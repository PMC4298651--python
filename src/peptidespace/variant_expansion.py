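"""Expand a sequence collection with one sequence per applicable variant.

Each single-amino-acid variant produces one additional full-length sequence
per record of its entry (canonical and isoforms) on which the stated
reference residue is verbatim present at the stated position. Isoform
coordinates are NOT remapped by alignment: the canonical-coordinate check
must pass on the isoform at the same position, which undercounts isoform
applications relative to alignment-aware expanders — a conservative, fully
testable choice. Variants never stack: one substitution per new sequence.

Expanded accessions are ``<source accession>|<feature id>`` so entry-level
accession parsing still recovers the source entry.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from peptidespace.digestion import DigestIndex
from peptidespace.sequence_io import (
    EXPANSION_SEPARATOR,
    ProteinRecord,
    VariantCategory,
    VariantRecord,
)


@dataclass(frozen=True)
class ExpandedRecord(ProteinRecord):
    """A variant-carrying copy of a source record (one substitution)."""

    source_accession: str = ""
    applied_feature_id: str = ""


@dataclass(frozen=True)
class ApplicationEvent:
    feature_id: str
    target_accession: str
    applied: bool
    reason: str  # "applied", "ref_mismatch", "position_out_of_range", "entry_not_found"
    target_is_isoform: bool = False


@dataclass
class ExpansionLog:
    events: list[ApplicationEvent] = field(default_factory=list)

    @property
    def applied(self) -> list[ApplicationEvent]:
        return [e for e in self.events if e.applied]

    @property
    def skipped(self) -> list[ApplicationEvent]:
        return [e for e in self.events if not e.applied]

    def applied_by_feature(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for e in self.applied:
            out.setdefault(e.feature_id, []).append(e.target_accession)
        return out

    def counts(self) -> dict[str, int]:
        """Summary: applications to canonical vs isoform targets, and skips."""
        c = Counter()
        for e in self.events:
            if e.applied:
                c["applied_isoform" if e.target_is_isoform else "applied_canonical"] += 1
            else:
                c[f"skipped_{e.reason}"] += 1
        return dict(c)


def expand_variants(
    records: Sequence[ProteinRecord],
    variants: Sequence[VariantRecord],
    mode: str = "all",
) -> tuple[list[ProteinRecord], ExpansionLog]:
    """Return the collection plus one expanded record per applied variant.

    ``mode='disease_only'`` restricts the expansion to variants annotated
    as disease-related; ``'all'`` applies every variant. Original records
    are always retained; skips are never fatal, only logged.
    """
    if mode not in ("all", "disease_only"):
        raise ValueError(f"unknown expansion mode {mode!r}")
    by_entry: dict[str, list[ProteinRecord]] = {}
    for rec in records:
        by_entry.setdefault(rec.entry_accession, []).append(rec)

    log = ExpansionLog()
    expanded: list[ProteinRecord] = []
    for v in variants:
        if mode == "disease_only" and v.category is not VariantCategory.disease:
            continue
        targets = by_entry.get(v.entry_accession)
        if not targets:
            log.events.append(
                ApplicationEvent(v.feature_id, v.entry_accession, False, "entry_not_found")
            )
            continue
        for rec in targets:
            pos = v.position - 1
            if pos >= len(rec.sequence):
                log.events.append(
                    ApplicationEvent(
                        v.feature_id, rec.accession, False,
                        "position_out_of_range", rec.is_isoform,
                    )
                )
                continue
            if rec.sequence[pos] != v.ref_aa:
                log.events.append(
                    ApplicationEvent(
                        v.feature_id, rec.accession, False,
                        "ref_mismatch", rec.is_isoform,
                    )
                )
                continue
            new_seq = rec.sequence[:pos] + v.alt_aa + rec.sequence[pos + 1 :]
            expanded.append(
                ExpandedRecord(
                    accession=f"{rec.accession}{EXPANSION_SEPARATOR}{v.feature_id}",
                    section=rec.section,
                    description=rec.description,
                    sequence=new_seq,
                    source_accession=rec.accession,
                    applied_feature_id=v.feature_id,
                )
            )
            log.events.append(
                ApplicationEvent(
                    v.feature_id, rec.accession, True, "applied", rec.is_isoform
                )
            )
    return list(records) + expanded, log


def is_variant_derived(accession: str) -> bool:
    return EXPANSION_SEPARATOR in accession


@dataclass(frozen=True)
class CoincidenceReport:
    """Peptide accounting for a variant expansion.

    * ``additional_peptides``: peptide sequences in the expanded digest but
      not in the base digest (the genuinely new search space).
    * ``coincident_with_other``: additional peptides that also occur in a
      second, independent collection's digest (chance sequence coincidence
      across databases).
    * ``coincident_within_base``: peptides produced by variant-carrying
      records whose sequence already exists in the base collection's own
      digest (chance coincidence within the collection; by construction
      these are not "additional").
    """

    additional_peptides: frozenset[str]
    coincident_with_other: frozenset[str]
    coincident_within_base: frozenset[str]

    @property
    def n_additional(self) -> int:
        return len(self.additional_peptides)


def coincident_peptide_report(
    base_index: DigestIndex,
    expanded_index: DigestIndex,
    other_index: Optional[DigestIndex] = None,
) -> CoincidenceReport:
    """Account for new and coincident peptides after a variant expansion."""
    base = base_index.peptides
    additional = expanded_index.peptides - base
    other = other_index.peptides if other_index is not None else frozenset()
    variant_peps = frozenset(
        pep
        for pep, occs in expanded_index.occurrences.items()
        if any(is_variant_derived(o.accession) for o in occs)
    )
    return CoincidenceReport(
        additional_peptides=frozenset(additional),
        coincident_with_other=frozenset(additional & other),
        coincident_within_base=frozenset(variant_peps & base),
    )


def write_expansion_log(
    log: ExpansionLog, path: Union[str, Path], header_lines: Sequence[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("feature_id\ttarget_accession\tstatus\treason\n")
        for e in log.events:
            status = "applied" if e.applied else "skipped"
            fh.write(f"{e.feature_id}\t{e.target_accession}\t{status}\t{e.reason}\n")
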