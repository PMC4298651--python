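"""I/O for protein collections, variant tables, and peptide-evidence lists.

Reads and writes the three plain-text dialects the pipeline touches:

* FASTA with UniProtKB-style headers (``>sp|P12345|ALBU_HUMAN Serum albumin``,
  ``sp`` = reviewed / Swiss-Prot, ``tr`` = unreviewed / TrEMBL) or plain
  headers (first whitespace-delimited token is the accession);
* a humsavar-like tab-separated single-amino-acid variant table;
* simple peptide-evidence tables as exported from MS proteomics repositories
  (PRIDE, PeptideAtlas, GPMDB).

Sequences are normalized to uppercase at ingest and validated against the
20 standard residues plus U (selenocysteine) and the ambiguity codes X, B, Z.
Anything else (``*``, ``-`` ...) is an error, never silently dropped.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Data.IUPACData import protein_letters_3to1_extended

from peptidespace.repository_evidence import EvidenceSet

log = logging.getLogger(__name__)

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
#: Full ingest alphabet: 20 standard residues, selenocysteine, ambiguity codes.
EXTENDED_AA = frozenset(STANDARD_AA) | frozenset("UXBZ")
#: Residues that make a peptide mass-indeterminate.
AMBIGUOUS_AA = frozenset("XBZ")

#: Separator appended by variant expansion: "P12345-2|VAR_000123".
EXPANSION_SEPARATOR = "|"

_ISOFORM_RE = re.compile(r"^(?P<base>.+?)-(?P<iso>[1-9][0-9]*)$")


class SequenceIOError(ValueError):
    """Malformed input file (header, residue letter, or table row)."""


class Section(str, Enum):
    reviewed = "reviewed"
    unreviewed = "unreviewed"
    other = "other"


class VariantCategory(str, Enum):
    disease = "disease"
    polymorphism = "polymorphism"
    unclassified = "unclassified"


def base_accession(accession: str) -> str:
    """Accession with any variant-expansion suffix (``|VAR_...``) removed."""
    return accession.split(EXPANSION_SEPARATOR, 1)[0]


def entry_accession_of(accession: str) -> str:
    """Entry accession: strips expansion suffix and isoform ``-n`` suffix."""
    acc = base_accession(accession)
    m = _ISOFORM_RE.match(acc)
    return m.group("base") if m else acc


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its accession and section metadata.

    ``entry_accession`` and ``is_isoform`` are derived: ``P12345-2`` is
    isoform 2 of entry ``P12345``; a variant-expanded accession
    ``P12345-2|VAR_000123`` still maps back to entry ``P12345``.
    """

    accession: str
    section: Section
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.accession:
            raise SequenceIOError("empty accession")
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.sequence:
            raise SequenceIOError(f"{self.accession}: empty sequence")
        for i, ch in enumerate(self.sequence):
            if ch not in EXTENDED_AA:
                raise SequenceIOError(
                    f"{self.accession}: illegal residue {ch!r} at offset {i}"
                )

    @property
    def entry_accession(self) -> str:
        return entry_accession_of(self.accession)

    @property
    def is_isoform(self) -> bool:
        return _ISOFORM_RE.match(base_accession(self.accession)) is not None

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# FASTA


def _parse_uniprot_header(header: str, record_no: int) -> tuple[str, Section, str]:
    token, _, rest = header.partition(" ")
    parts = token.split("|")
    if len(parts) < 3 or parts[0] not in ("sp", "tr"):
        raise SequenceIOError(
            f"record {record_no}: malformed UniProtKB header {header!r} "
            "(expected 'sp|ACC|NAME' or 'tr|ACC|NAME')"
        )
    section = Section.reviewed if parts[0] == "sp" else Section.unreviewed
    # Variant-expanded accessions embed '|', giving >3 fields; the name token
    # is always the last field and never contains '|'.
    accession = "|".join(parts[1:-1])
    name = parts[-1]
    description = f"{name} {rest}".strip() if rest else name
    return accession, section, description


def read_fasta(
    path: Union[str, Path], header_dialect: str = "uniprot"
) -> list[ProteinRecord]:
    """Read a FASTA file into an ordered list of :class:`ProteinRecord`.

    ``header_dialect='uniprot'`` parses ``sp|ACC|NAME`` / ``tr|ACC|NAME``
    into section and accession; ``'plain'`` takes the first whitespace token
    as accession and sets section ``other`` (Ensembl/RefSeq/IPI-style files).
    Duplicate accessions are rejected.
    """
    if header_dialect not in ("uniprot", "plain"):
        raise ValueError(f"unknown header dialect {header_dialect!r}")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for record_no, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        header = rec.description
        if header_dialect == "uniprot":
            accession, section, description = _parse_uniprot_header(header, record_no)
        else:
            token, _, rest = header.partition(" ")
            if not token:
                raise SequenceIOError(f"record {record_no}: empty header")
            accession, section, description = token, Section.other, rest.strip()
        if accession in seen:
            raise SequenceIOError(
                f"record {record_no}: duplicate accession {accession!r}"
            )
        seen.add(accession)
        records.append(ProteinRecord(accession, section, description, str(rec.seq)))
    return records


_SECTION_TO_DB = {Section.reviewed: "sp", Section.unreviewed: "tr"}


def write_fasta(
    records: Iterable[ProteinRecord],
    path: Union[str, Path],
    header_dialect: str = "uniprot",
    width: int = 60,
) -> None:
    """Write records in the given header dialect (wrap sequences at *width*).

    The uniprot dialect stores the record description verbatim after the
    ``db|ACC|`` prefix, so its first word acts as the entry-name token and
    must not contain ``'|'``; section ``other`` has no db token and cannot
    be written in this dialect.
    """
    with open(path, "w") as fh:
        for r in records:
            if header_dialect == "uniprot":
                if r.section not in _SECTION_TO_DB:
                    raise ValueError(
                        f"{r.accession}: section {r.section.value!r} has no "
                        "UniProtKB db token; use the plain dialect"
                    )
                first_word = r.description.split(None, 1)[0] if r.description else ""
                if "|" in first_word:
                    raise ValueError(
                        f"{r.accession}: description name token contains '|'"
                    )
                header = f">{_SECTION_TO_DB[r.section]}|{r.accession}|{r.description}"
            elif header_dialect == "plain":
                header = f">{r.accession}"
                if r.description:
                    header += f" {r.description}"
            else:
                raise ValueError(f"unknown header dialect {header_dialect!r}")
            fh.write(header + "\n")
            for i in range(0, len(r.sequence), width):
                fh.write(r.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Variants


@dataclass(frozen=True)
class VariantRecord:
    """A single-amino-acid substitution annotated on a UniProtKB entry."""

    entry_accession: str
    feature_id: str
    position: int  # 1-based on the stated (canonical) sequence
    ref_aa: str
    alt_aa: str
    category: VariantCategory = VariantCategory.unclassified
    disease_name: Optional[str] = None
    dbsnp: Optional[str] = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise SequenceIOError(f"{self.feature_id}: position must be >= 1")
        for aa in (self.ref_aa, self.alt_aa):
            if len(aa) != 1 or aa not in EXTENDED_AA:
                raise SequenceIOError(f"{self.feature_id}: bad residue {aa!r}")
        if self.ref_aa == self.alt_aa:
            raise SequenceIOError(
                f"{self.feature_id}: reference and alternate residue are both "
                f"{self.ref_aa!r}"
            )

    @property
    def is_il_variant(self) -> bool:
        """True for I<->L swaps, invisible to standard MS workflows."""
        return {self.ref_aa, self.alt_aa} <= {"I", "L"}

    @property
    def change(self) -> str:
        return f"{self.ref_aa}{self.position}{self.alt_aa}"


_CHANGE_ONE = re.compile(r"^([A-Z])(\d+)([A-Z])$")
_CHANGE_THREE = re.compile(r"^p\.([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})$")
_THREE_TO_ONE = {k: v for k, v in protein_letters_3to1_extended.items()}


def parse_change(change: str) -> tuple[str, int, str]:
    """Parse ``'D123N'`` or ``'p.Asp123Asn'`` into (ref, position, alt)."""
    m = _CHANGE_ONE.match(change)
    if m:
        return m.group(1), int(m.group(2)), m.group(3)
    m = _CHANGE_THREE.match(change)
    if m:
        try:
            ref = _THREE_TO_ONE[m.group(1)]
            alt = _THREE_TO_ONE[m.group(3)]
        except KeyError as exc:
            raise SequenceIOError(
                f"unknown three-letter residue code in {change!r}"
            ) from exc
        return ref, int(m.group(2)), alt
    raise SequenceIOError(f"unparseable change token {change!r}")


def read_variants(path: Union[str, Path]) -> list[VariantRecord]:
    """Read a humsavar-like TSV (``#`` comment lines ignored).

    Required columns: entry_accession, feature_id, change, category.
    Optional: disease, dbsnp. Unknown category strings map to
    ``unclassified`` with a logged warning.
    """
    df = pd.read_csv(
        str(path), sep="\t", comment="#", dtype=str, keep_default_na=False
    )
    required = {"entry_accession", "feature_id", "change", "category"}
    missing = required - set(df.columns)
    if missing:
        raise SequenceIOError(f"variant table missing columns: {sorted(missing)}")
    out: list[VariantRecord] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            ref, pos, alt = parse_change(row.change)
        except SequenceIOError as exc:
            raise SequenceIOError(f"row {row_no}: {exc}") from exc
        cat_str = row.category.strip().lower()
        try:
            category = VariantCategory(cat_str)
        except ValueError:
            log.warning(
                "row %d: unknown variant category %r mapped to 'unclassified'",
                row_no,
                row.category,
            )
            category = VariantCategory.unclassified
        disease = getattr(row, "disease", "") or None
        dbsnp = getattr(row, "dbsnp", "") or None
        try:
            out.append(
                VariantRecord(
                    entry_accession=row.entry_accession,
                    feature_id=row.feature_id,
                    position=pos,
                    ref_aa=ref,
                    alt_aa=alt,
                    category=category,
                    disease_name=disease,
                    dbsnp=dbsnp,
                )
            )
        except SequenceIOError as exc:
            raise SequenceIOError(f"row {row_no}: {exc}") from exc
    return out


def write_variants(
    variants: Iterable[VariantRecord],
    path: Union[str, Path],
    header_lines: Sequence[str] = (),
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("entry_accession\tfeature_id\tchange\tcategory\tdisease\tdbsnp\n")
        for v in variants:
            fh.write(
                f"{v.entry_accession}\t{v.feature_id}\t{v.change}\t"
                f"{v.category.value}\t{v.disease_name or ''}\t{v.dbsnp or ''}\n"
            )


# ---------------------------------------------------------------------------
# Evidence


def read_evidence(path: Union[str, Path], repository: str) -> EvidenceSet:
    """Read a peptide-evidence TSV into an :class:`EvidenceSet`.

    Column ``peptide`` is required; ``experiment_count`` is optional and
    defaults to 1. Duplicate peptide rows are collapsed by summing counts.
    An empty file yields an empty set with a warning.
    """
    try:
        df = pd.read_csv(
            str(path), sep="\t", comment="#", dtype=str, keep_default_na=False
        )
    except pd.errors.EmptyDataError:
        log.warning("evidence file %s is empty", path)
        return EvidenceSet(repository=repository, counts={}, provenance=str(path))
    if "peptide" not in df.columns:
        raise SequenceIOError(f"evidence table {path} has no 'peptide' column")
    counts: dict[str, int] = {}
    for row in df.itertuples(index=False):
        pep = row.peptide.strip().upper()
        if not pep:
            continue
        raw = getattr(row, "experiment_count", "")
        n = int(raw) if raw else 1
        counts[pep] = counts.get(pep, 0) + n
    if not counts:
        log.warning("evidence file %s contains no peptides", path)
    return EvidenceSet(repository=repository, counts=counts, provenance=str(path))


def write_evidence(
    evidence: EvidenceSet, path: Union[str, Path], header_lines: Sequence[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("peptide\texperiment_count\n")
        for pep in sorted(evidence.counts):
            fh.write(f"{pep}\t{evidence.counts[pep]}\n")
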