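"""In-silico tryptic digestion, peptide indexing, and monoisotopic masses.

The digestion model is the one conventional for search-space accounting:
full tryptic cleavage C-terminal to K or R (``trypsin`` suppresses cleavage
when the next residue is proline; ``trypsin_p`` cleaves regardless), zero
missed cleavages by default, no initiator-methionine trimming (Met-trimmed
peptide variants are never generated), and a minimum peptide length of six
residues — shorter peptides are rarely observed in bottom-up MS and carry
little sequence-specific information. A sequence ending without K/R yields
a C-terminal non-tryptic-end peptide, which is retained. The ambiguity
codes B, Z, X are never cleavage sites; only literal K/R cleave.

Monoisotopic masses use the pyteomics ``std_aa_mass`` residue table
(monoisotopic, >=5 decimals; U = 150.95363 Da for selenocysteine) plus one
water. Peptides containing X, B or Z have indeterminate mass (``None``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from pyteomics import mass as _pmass

from peptidespace.sequence_io import AMBIGUOUS_AA, ProteinRecord

#: Monoisotopic residue masses (pyteomics std_aa_mass).
RESIDUE_MASS: Mapping[str, float] = dict(_pmass.std_aa_mass)
WATER_MONO: float = _pmass.calculate_mass(formula="H2O")


class CleavageRule(str, Enum):
    trypsin = "trypsin"  # after K/R, not before P (Keil rule)
    trypsin_p = "trypsin_p"  # after every K/R


@dataclass(frozen=True)
class DigestionConfig:
    rule: CleavageRule = CleavageRule.trypsin
    missed_cleavages: int = 0
    min_length: int = 6
    max_length: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "rule", CleavageRule(self.rule))
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")
        if self.max_length is not None and self.max_length < self.min_length:
            raise ValueError("max_length must be >= min_length")


DEFAULT_CONFIG = DigestionConfig()


def is_ambiguous(peptide: str) -> bool:
    return not AMBIGUOUS_AA.isdisjoint(peptide)


def mono_mass(peptide: str) -> Optional[float]:
    """Monoisotopic peptide mass in Da, or None when X/B/Z make it indeterminate."""
    if not peptide:
        raise ValueError("empty peptide")
    if is_ambiguous(peptide):
        return None
    try:
        return sum(RESIDUE_MASS[aa] for aa in peptide) + WATER_MONO
    except KeyError as exc:
        raise ValueError(f"unknown residue in {peptide!r}") from exc


@dataclass(frozen=True)
class Peptide:
    """A peptide sequence with derived length, ambiguity and mass."""

    sequence: str
    length: int
    is_ambiguous: bool
    mono_mass: Optional[float]

    @classmethod
    def from_sequence(cls, sequence: str) -> "Peptide":
        ambiguous = is_ambiguous(sequence)
        return cls(
            sequence=sequence,
            length=len(sequence),
            is_ambiguous=ambiguous,
            mono_mass=None if ambiguous else mono_mass(sequence),
        )


def cleavage_sites(sequence: str, rule: CleavageRule) -> list[int]:
    """Cut positions (0 and len included) for a sequence under a rule."""
    n = len(sequence)
    sites = [0]
    for i in range(n):
        if sequence[i] in "KR":
            if (
                rule is CleavageRule.trypsin_p
                or i + 1 == n
                or sequence[i + 1] != "P"
            ):
                sites.append(i + 1)
    if sites[-1] != n:
        sites.append(n)
    return sites


def digest_sequence(
    sequence: str, config: DigestionConfig = DEFAULT_CONFIG
) -> list[tuple[str, int]]:
    """Digest one sequence into an ordered list of (peptide, 0-based offset).

    With ``missed_cleavages = m`` every concatenation of up to m+1
    consecutive fully-cleaved fragments is emitted. Ordered by offset,
    then by increasing length.
    """
    if not sequence:
        raise ValueError("empty sequence")
    sequence = sequence.upper()
    sites = cleavage_sites(sequence, config.rule)
    out: list[tuple[str, int]] = []
    m = config.missed_cleavages
    for j in range(len(sites) - 1):
        start = sites[j]
        for k in range(j + 1, min(j + 2 + m, len(sites))):
            pep = sequence[start : sites[k]]
            if len(pep) < config.min_length:
                continue
            if config.max_length is not None and len(pep) > config.max_length:
                break  # longer spans only get longer
            out.append((pep, start))
    return out


@dataclass(frozen=True)
class Occurrence:
    accession: str
    offset: int  # 0-based start


@dataclass
class DigestIndex:
    """Mapping peptide sequence -> occurrences across a digested collection."""

    config: DigestionConfig
    occurrences: dict[str, tuple[Occurrence, ...]] = field(default_factory=dict)

    @property
    def peptides(self) -> frozenset[str]:
        return frozenset(self.occurrences)

    def accessions_of(self, peptide: str) -> frozenset[str]:
        return frozenset(o.accession for o in self.occurrences.get(peptide, ()))

    def __len__(self) -> int:
        return len(self.occurrences)

    def __contains__(self, peptide: str) -> bool:
        return peptide in self.occurrences


def digest_collection(
    records: Sequence[ProteinRecord], config: DigestionConfig = DEFAULT_CONFIG
) -> DigestIndex:
    """Digest every record and index all peptide occurrences.

    Iteration order is deterministic: occurrences sorted by accession,
    then offset.
    """
    if not records:
        raise ValueError("empty collection")
    acc: dict[str, list[Occurrence]] = {}
    for rec in sorted(records, key=lambda r: r.accession):
        for pep, offset in digest_sequence(rec.sequence, config):
            acc.setdefault(pep, []).append(Occurrence(rec.accession, offset))
    return DigestIndex(
        config=config,
        occurrences={p: tuple(v) for p, v in acc.items()},
    )


def write_digest_tsv(
    index: DigestIndex, path: Union[str, Path], header_lines: Sequence[str] = ()
) -> None:
    """Peptide list TSV: peptide, length, mono_mass, n_occurrences, accessions."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("peptide\tlength\tmono_mass\tn_occurrences\taccessions\n")
        for pep in sorted(index.occurrences):
            occs = index.occurrences[pep]
            m = mono_mass(pep)
            mass_str = f"{m:.4f}" if m is not None else ""
            accs = ";".join(sorted({o.accession for o in occs}))
            fh.write(f"{pep}\t{len(pep)}\t{mass_str}\t{len(occs)}\t{accs}\n")
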