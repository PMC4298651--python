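"""100%-identity redundancy clustering and lost-peptide accounting.

Two records are linked when their sequences are equal or one is a
contiguous substring of the other (UniRef100-style semantics: identical
sequences and subfragments collapse onto one representative). Clusters are
the connected components of that relation; the representative is the
longest sequence (ties broken by lexicographically smallest sequence, then
smallest accession), which makes the clustering deterministic.

Collapsing a fragment whose ends fall mid-peptide destroys the fragment's
terminal peptides: they are producible from the member but not from any
representative. ``lost_peptides`` computes exactly that set and classifies
each loss by where the occurrence sat on the member (N-terminal start,
C-terminal end, or internal). ``dedup_exact`` removes only
identical-sequence records and therefore provably loses no peptides.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence, Union

from peptidespace.digestion import DigestionConfig, DEFAULT_CONFIG, digest_sequence
from peptidespace.sequence_io import ProteinRecord


@dataclass(frozen=True)
class Cluster:
    representative_accession: str
    member_accessions: frozenset[str]  # includes the representative

    def __len__(self) -> int:
        return len(self.member_accessions)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def cluster_collection(
    records: Sequence[ProteinRecord], min_fragment_length: int = 1
) -> tuple[list[Cluster], list[ProteinRecord]]:
    """Cluster by sequence identity/containment; return (clusters, reduced).

    ``min_fragment_length`` sets the shortest subfragment that may be
    merged into a longer sequence (identical sequences always merge). The
    reduced collection holds one representative record per cluster, in the
    original record order of the representatives.

    Substring candidates are prefiltered with a k-mer index over the
    longer sequences, so typical collections cluster in near-linear time.
    """
    n = len(records)
    uf = _UnionFind(n)

    # exact duplicates
    first_by_seq: dict[str, int] = {}
    for i, rec in enumerate(records):
        j = first_by_seq.setdefault(rec.sequence, i)
        if j != i:
            uf.union(j, i)

    # containment: process unique sequences longest-first; look shorter
    # sequences up against a k-mer index of the already-seen longer ones.
    uniq = sorted(first_by_seq.items(), key=lambda kv: (-len(kv[0]), kv[0]))
    K = 10
    kmer_index: dict[str, list[int]] = {}
    seen: list[tuple[str, int]] = []  # (sequence, record index), longest first
    for seq, idx in uniq:
        if len(seq) >= min_fragment_length:
            if len(seq) >= K:
                candidates = kmer_index.get(seq[:K], ())
            else:
                candidates = [i for _, i in seen]
            for cand in candidates:
                cand_seq = records[cand].sequence
                if len(cand_seq) > len(seq) and seq in cand_seq:
                    uf.union(cand, idx)
        if len(seq) >= K:
            for p in range(len(seq) - K + 1):
                kmer_index.setdefault(seq[p : p + K], []).append(idx)
        seen.append((seq, idx))

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)

    clusters: list[Cluster] = []
    rep_indices: list[int] = []
    for members in groups.values():
        rep = min(
            members,
            key=lambda i: (-len(records[i].sequence), records[i].sequence,
                           records[i].accession),
        )
        rep_indices.append(rep)
        clusters.append(
            Cluster(
                representative_accession=records[rep].accession,
                member_accessions=frozenset(records[i].accession for i in members),
            )
        )
    rep_indices.sort()
    reduced = [records[i] for i in rep_indices]
    clusters.sort(key=lambda c: c.representative_accession)
    return clusters, reduced


class TerminalClass(str, Enum):
    n_terminal = "n_terminal"
    c_terminal = "c_terminal"
    internal = "internal"


@dataclass(frozen=True)
class LostPeptide:
    peptide: str
    member_accession: str
    terminal_class: TerminalClass


@dataclass
class LostPeptideReport:
    rows: list[LostPeptide]

    @property
    def peptides(self) -> frozenset[str]:
        return frozenset(r.peptide for r in self.rows)

    def __len__(self) -> int:
        return len(self.rows)


def lost_peptides(
    clusters: Sequence[Cluster],
    records: Sequence[ProteinRecord],
    config: DigestionConfig = DEFAULT_CONFIG,
) -> LostPeptideReport:
    """Peptides producible from cluster members but from no representative.

    Each lost peptide is classified per contributing member by occurrence
    position: ``n_terminal`` when it starts at the member's first residue,
    ``c_terminal`` when it ends at the last, ``internal`` otherwise (a
    peptide may carry several classes via different members/occurrences).
    """
    by_acc = {r.accession: r for r in records}
    digests: dict[str, list[tuple[str, int]]] = {}

    def digest_of(accession: str) -> list[tuple[str, int]]:
        if accession not in digests:
            digests[accession] = digest_sequence(by_acc[accession].sequence, config)
        return digests[accession]

    rep_peptides: set[str] = set()
    for cluster in clusters:
        rep_peptides.update(p for p, _ in digest_of(cluster.representative_accession))

    rows: list[LostPeptide] = []
    seen: set[tuple[str, str, TerminalClass]] = set()
    for cluster in sorted(clusters, key=lambda c: c.representative_accession):
        for member in sorted(cluster.member_accessions):
            seq_len = len(by_acc[member].sequence)
            for pep, offset in digest_of(member):
                if pep in rep_peptides:
                    continue
                if offset == 0:
                    cls = TerminalClass.n_terminal
                elif offset + len(pep) == seq_len:
                    cls = TerminalClass.c_terminal
                else:
                    cls = TerminalClass.internal
                key = (pep, member, cls)
                if key not in seen:
                    seen.add(key)
                    rows.append(LostPeptide(pep, member, cls))
    return LostPeptideReport(rows=rows)


def dedup_exact(records: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """Drop records whose sequence duplicates an earlier one (zero peptide loss)."""
    seen: set[str] = set()
    out: list[ProteinRecord] = []
    for rec in records:
        if rec.sequence not in seen:
            seen.add(rec.sequence)
            out.append(rec)
    return out


def write_cluster_tsv(
    clusters: Sequence[Cluster],
    records: Sequence[ProteinRecord],
    path: Union[str, Path],
    header_lines: Sequence[str] = (),
) -> None:
    by_acc = {r.accession: r for r in records}
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("representative\tmember\trelation\n")
        for cluster in sorted(clusters, key=lambda c: c.representative_accession):
            rep_seq = by_acc[cluster.representative_accession].sequence
            for member in sorted(cluster.member_accessions):
                relation = (
                    "identical" if by_acc[member].sequence == rep_seq else "fragment"
                )
                fh.write(f"{cluster.representative_accession}\t{member}\t{relation}\n")


def write_lost_peptide_tsv(
    report: LostPeptideReport, path: Union[str, Path], header_lines: Sequence[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("peptide\tmember_accession\tterminal_class\n")
        for row in sorted(
            report.rows, key=lambda r: (r.peptide, r.member_accession, r.terminal_class)
        ):
            fh.write(f"{row.peptide}\t{row.member_accession}\t{row.terminal_class.value}\n")
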