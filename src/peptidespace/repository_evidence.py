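"""MS proteomics repository peptide evidence: filtering, merging, querying.

An :class:`EvidenceSet` holds the peptides reported by one repository
(PRIDE, PeptideAtlas, GPMDB, ...) with per-peptide experiment counts.
PRIDE-style sets are conventionally filtered to peptides seen in at least
five experiments to compensate for submission heterogeneity; PeptideAtlas
and GPMDB builds are used as provided (counts of 1).

Matching against digest peptides is exact full-length string equality after
uppercase normalization; I and L are deliberately NOT equated and no mass
tolerance is applied — anything looser would inflate evidence percentages.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence


@dataclass
class EvidenceSet:
    """Peptides reported by one repository, with experiment counts."""

    repository: str
    counts: dict[str, int] = field(default_factory=dict)
    provenance: str = ""

    @property
    def peptides(self) -> frozenset[str]:
        return frozenset(self.counts)

    def __contains__(self, peptide: str) -> bool:
        return peptide in self.counts

    def __len__(self) -> int:
        return len(self.counts)


def filter_min_experiments(evidence: EvidenceSet, min_count: int) -> EvidenceSet:
    """Keep peptides identified in at least *min_count* experiments.

    Idempotent, and monotone decreasing in *min_count*.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    kept = {p: n for p, n in evidence.counts.items() if n >= min_count}
    note = f"{evidence.provenance}; filtered >= {min_count} experiments".lstrip("; ")
    return EvidenceSet(repository=evidence.repository, counts=kept, provenance=note)


def merge_evidence(
    evidence_sets: Sequence[EvidenceSet], repository: str = "merged"
) -> EvidenceSet:
    """Union of several evidence sets; experiment counts are summed."""
    counts: Counter[str] = Counter()
    for ev in evidence_sets:
        counts.update(ev.counts)
    prov = " + ".join(ev.repository for ev in evidence_sets)
    return EvidenceSet(repository=repository, counts=dict(counts), provenance=prov)


@dataclass(frozen=True)
class LookupResult:
    matched: frozenset[str]
    per_repository: Mapping[str, frozenset[str]]


def evidence_lookup(
    peptides: Iterable[str],
    evidence_sets: Sequence[EvidenceSet],
    mode: str = "any",
) -> LookupResult:
    """Query peptides against repositories by exact full-length match.

    ``mode='any'`` keeps peptides present in at least one set; ``'all'``
    keeps peptides concurrently present in every set (the three-repository
    intersection analysis). The 'all' result is always a subset of 'any'.
    """
    if mode not in ("any", "all"):
        raise ValueError(f"unknown lookup mode {mode!r}")
    query = {p.upper() for p in peptides}
    per_repo = {
        ev.repository: frozenset(query & ev.peptides) for ev in evidence_sets
    }
    if not evidence_sets:
        matched: frozenset[str] = frozenset()
    elif mode == "any":
        matched = frozenset().union(*per_repo.values())
    else:
        matched = frozenset.intersection(*per_repo.values())
    return LookupResult(matched=matched, per_repository=per_repo)


@dataclass(frozen=True)
class LengthProfile:
    max_length: int
    histogram: Mapping[int, int]


def length_profile(evidence: EvidenceSet) -> LengthProfile:
    """Maximum peptide length and length histogram of an evidence set.

    Repository length ceilings motivate capping unicity analyses (e.g. at
    66 residues, the longest fully tryptic peptide the major repositories
    held at the time of the original survey).
    """
    hist = Counter(len(p) for p in evidence.counts)
    return LengthProfile(max_length=max(hist) if hist else 0, histogram=dict(hist))
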