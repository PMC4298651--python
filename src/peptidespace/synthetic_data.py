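"""Synthetic proteome generator with a ground-truth manifest.

Emulates the structure of an organism-specific UniProtKB-style collection
so that every pipeline stage is testable without downloading a database
release: reviewed canonical entries with isoforms (derived by deleting one
internal exon-like block, which guarantees isoform-specific junction
peptides), single-amino-acid variants with a disease-labelled subset and a
small I/L-swap fraction, planted exact-duplicate and subfragment records
(the redundancy that 100%-identity clustering removes), rare ambiguous
residues (X/B/Z), and per-repository peptide evidence sampled from the
true digest with geometric experiment counts plus decoy peptides.

Amino-acid composition follows Swiss-Prot background frequencies with the
combined K+R frequency rescaled to 8%, putting the mean tryptic peptide
length near 12 residues. Generation is fully deterministic under a seed.

The :class:`GroundTruthManifest` predicts — without running the pipeline —
cluster membership, variant application/skip outcomes, lost and unique
peptide sets, and repository evidence membership; :func:`recovery_suite`
runs the pipeline against those predictions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy import stats

from peptidespace.digestion import (
    DEFAULT_CONFIG,
    DigestionConfig,
    digest_collection,
    digest_sequence,
)
from peptidespace.redundancy_clustering import (
    cluster_collection,
    dedup_exact,
    lost_peptides,
)
from peptidespace.repository_evidence import EvidenceSet
from peptidespace.sequence_io import (
    STANDARD_AA,
    ProteinRecord,
    Section,
    VariantCategory,
    VariantRecord,
    write_evidence,
    write_fasta,
    write_variants,
)
from peptidespace.unicity import unicity_report
from peptidespace.variant_expansion import expand_variants

# Swiss-Prot background amino-acid frequencies (percent), K+R rescaled below.
_BASE_FREQ = {
    "A": 8.25, "C": 1.38, "D": 5.46, "E": 6.72, "F": 3.86,
    "G": 7.07, "H": 2.27, "I": 5.91, "K": 5.80, "L": 9.65,
    "M": 2.41, "N": 4.06, "P": 4.74, "Q": 3.93, "R": 5.53,
    "S": 6.64, "T": 5.35, "V": 6.86, "W": 1.10, "Y": 2.92,
}
_KR_TARGET = 0.08  # mean tryptic peptide length ~ 1 / 0.08 = 12.5 residues


def _aa_distribution() -> tuple[str, np.ndarray]:
    letters = "".join(sorted(_BASE_FREQ))
    freq = np.array([_BASE_FREQ[a] for a in letters], dtype=float)
    freq /= freq.sum()
    kr = np.array([a in "KR" for a in letters])
    scale = _KR_TARGET / freq[kr].sum()
    freq[kr] *= scale
    freq[~kr] *= (1.0 - _KR_TARGET) / freq[~kr].sum()
    return letters, freq


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic proteome."""

    seed: int = 0
    n_entries: int = 60
    mean_length: float = 350.0
    sd_length: float = 120.0
    min_seq_length: int = 80
    isoform_probability: float = 0.4
    max_isoforms: int = 2
    variant_rate: float = 1.5  # Poisson mean per entry
    disease_fraction: float = 0.3
    il_variant_fraction: float = 0.005  # fraction of variants that are I/L swaps
    duplicate_rate: float = 0.15
    fragment_rate: float = 0.15
    ambiguous_residue_rate: float = 0.0005
    evidence_sampling: Mapping[str, float] = field(
        default_factory=lambda: {"PRIDE": 0.30, "PeptideAtlas": 0.25, "GPMDB": 0.20}
    )
    experiment_count_p: float = 0.35  # geometric success parameter, counts >= 1
    decoy_evidence_rate: float = 0.02
    digestion: DigestionConfig = DEFAULT_CONFIG

    def validate(self) -> None:
        rates = {
            "isoform_probability": self.isoform_probability,
            "disease_fraction": self.disease_fraction,
            "il_variant_fraction": self.il_variant_fraction,
            "duplicate_rate": self.duplicate_rate,
            "fragment_rate": self.fragment_rate,
            "ambiguous_residue_rate": self.ambiguous_residue_rate,
            "decoy_evidence_rate": self.decoy_evidence_rate,
            "experiment_count_p": self.experiment_count_p,
            **{f"evidence_sampling[{k}]": v for k, v in self.evidence_sampling.items()},
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.n_entries < 1:
            raise ValueError("n_entries must be >= 1")
        if self.variant_rate < 0:
            raise ValueError("variant_rate must be >= 0")
        if self.max_isoforms < 1:
            raise ValueError("max_isoforms must be >= 1")
        if self.min_seq_length < 20:
            raise ValueError("min_seq_length must be >= 20")


@dataclass
class GroundTruthManifest:
    """Everything needed to predict pipeline outputs without running it."""

    isoforms: dict[str, list[str]]  # entry accession -> isoform accessions
    variant_applications: dict[str, dict[str, list]]  # feature -> applied/skipped
    planted_pairs: list[tuple[str, str, str]]  # (source, clone, relation)
    expected_lost_peptides: frozenset[str]
    expected_unique_peptides: frozenset[str]
    per_accession_unique: dict[str, int]
    evidence_membership: dict[str, dict[str, list[str]]]  # repo -> true/decoy


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    records: list[ProteinRecord]
    variants: list[VariantRecord]
    evidence_sets: dict[str, EvidenceSet]
    manifest: GroundTruthManifest


def _random_sequence(rng: np.random.Generator, length: int,
                     letters: str, freq: np.ndarray) -> str:
    body = rng.choice(list(letters), size=length - 1, p=freq)
    return "M" + "".join(body)


def generate(config: SyntheticConfig = SyntheticConfig()) -> SyntheticDataset:
    """Generate a proteome, variant table, evidence sets, and manifest."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    letters, freq = _aa_distribution()

    records: list[ProteinRecord] = []
    isoforms: dict[str, list[str]] = {}
    planted_pairs: list[tuple[str, str, str]] = []
    canonicals: dict[str, str] = {}

    for i in range(config.n_entries):
        acc = f"P{10000 + i:05d}"
        length = max(
            config.min_seq_length,
            int(round(rng.normal(config.mean_length, config.sd_length))),
        )
        seq = list(_random_sequence(rng, length, letters, freq))
        # sparse ambiguity-code injection (never at the initiator)
        for pos in range(1, length):
            if rng.random() < config.ambiguous_residue_rate:
                seq[pos] = "XBZ"[rng.integers(0, 3)]
        sequence = "".join(seq)
        canonicals[acc] = sequence
        records.append(ProteinRecord(acc, Section.reviewed, f"SYN{i:05d} synthetic protein {i}", sequence))

        if rng.random() < config.isoform_probability and length >= 120:
            n_iso = int(rng.integers(1, config.max_isoforms + 1))
            for k in range(n_iso):
                # exon-like deletion of one internal block
                block = int(rng.integers(15, 61))
                start = int(rng.integers(20, max(21, length - block - 40)))
                iso_seq = sequence[:start] + sequence[start + block :]
                iso_acc = f"{acc}-{k + 2}"
                records.append(
                    ProteinRecord(
                        iso_acc, Section.reviewed,
                        f"SYN{i:05d} synthetic protein {i} isoform {k + 2}", iso_seq,
                    )
                )
                isoforms.setdefault(acc, []).append(iso_acc)

    # planted redundancy: exact duplicates and internal subfragments
    for i, (acc, sequence) in enumerate(sorted(canonicals.items())):
        if rng.random() < config.duplicate_rate:
            dup_acc = f"Q{50000 + i:05d}"
            records.append(
                ProteinRecord(
                    dup_acc, Section.unreviewed,
                    f"DUP{i:05d} duplicate of {acc}", sequence,
                )
            )
            planted_pairs.append((acc, dup_acc, "identical"))
        if rng.random() < config.fragment_rate and len(sequence) >= 150:
            # trim both ends, typically mid-peptide, keeping >= 60 residues
            start = int(rng.integers(3, len(sequence) // 4))
            end = int(rng.integers(3 * len(sequence) // 4, len(sequence) - 2))
            frag_acc = f"T{70000 + i:05d}"
            records.append(
                ProteinRecord(
                    frag_acc, Section.unreviewed,
                    f"FRG{i:05d} fragment of {acc}", sequence[start:end],
                )
            )
            planted_pairs.append((acc, frag_acc, "fragment"))

    # variants on canonical coordinates; ref always matches the canonical
    variants: list[VariantRecord] = []
    feature_no = 1
    for acc in sorted(canonicals):
        sequence = canonicals[acc]
        n_var = int(rng.poisson(config.variant_rate))
        for _ in range(n_var):
            want_il = rng.random() < config.il_variant_fraction
            il_positions = [
                p for p in range(1, len(sequence)) if sequence[p] in "IL"
            ]
            if want_il and il_positions:
                pos = int(il_positions[rng.integers(0, len(il_positions))])
                ref = sequence[pos]
                alt = "L" if ref == "I" else "I"
            else:
                for _attempt in range(50):
                    pos = int(rng.integers(1, len(sequence)))
                    ref = sequence[pos]
                    if ref in STANDARD_AA:
                        break
                else:
                    continue
                choices = [a for a in STANDARD_AA if a != ref]
                alt = choices[rng.integers(0, len(choices))]
            u = rng.random()
            if u < config.disease_fraction:
                category = VariantCategory.disease
                disease = f"Synthetic disease {feature_no}"
            elif u < config.disease_fraction + 0.9 * (1 - config.disease_fraction):
                category, disease = VariantCategory.polymorphism, None
            else:
                category, disease = VariantCategory.unclassified, None
            variants.append(
                VariantRecord(
                    entry_accession=acc,
                    feature_id=f"VAR_{feature_no:06d}",
                    position=pos + 1,
                    ref_aa=ref,
                    alt_aa=alt,
                    category=category,
                    disease_name=disease,
                    dbsnp=f"rs{int(rng.integers(10**6, 10**8))}",
                )
            )
            feature_no += 1

    # ---- manifest predictions (definitional set operations on the plan) ----
    index = digest_collection(records, config.digestion)
    all_peptides = sorted(index.peptides)

    # Predict cluster structure from the planted relations alone. Identity or
    # containment can only arise within one entry's family (canonical,
    # isoforms, planted duplicate/fragment): a fragment may also sit inside
    # an isoform when it avoids the isoform's deleted block, pulling the
    # isoform into the cluster transitively. Cross-family containment of
    # independent random sequences (>= 80 residues) is ignored as impossible.
    clone_src = {clone: src for src, clone, _ in planted_pairs}
    families: dict[str, list[ProteinRecord]] = {}
    for r in records:
        key = clone_src.get(r.accession, r.entry_accession)
        families.setdefault(key, []).append(r)
    removed: set[str] = set()
    for members in families.values():
        parent = {r.accession: r.accession for r in members}

        def find(a: str) -> str:
            while parent[a] != a:
                a = parent[a]
            return a

        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                sa, sb = a.sequence, b.sequence
                if sa == sb or sa in sb or sb in sa:
                    parent[find(b.accession)] = find(a.accession)
        comps: dict[str, list[ProteinRecord]] = {}
        for r in members:
            comps.setdefault(find(r.accession), []).append(r)
        for comp in comps.values():
            rep = min(comp, key=lambda r: (-len(r.sequence), r.sequence, r.accession))
            removed.update(r.accession for r in comp if r.accession != rep.accession)
    rep_pep: set[str] = set()
    for r in records:
        if r.accession not in removed:
            rep_pep.update(p for p, _ in digest_sequence(r.sequence, config.digestion))
    expected_lost = frozenset(index.peptides - rep_pep)

    expected_unique: set[str] = set()
    per_acc_unique: dict[str, int] = {}
    for pep, occs in index.occurrences.items():
        accs = {o.accession for o in occs}
        if len(accs) == 1 and not set("XBZ") & set(pep):
            expected_unique.add(pep)
            acc = next(iter(accs))
            per_acc_unique[acc] = per_acc_unique.get(acc, 0) + 1

    # predicted variant applications under the verbatim same-position rule
    variant_applications: dict[str, dict[str, list]] = {}
    by_entry: dict[str, list[ProteinRecord]] = {}
    for r in records:
        by_entry.setdefault(r.entry_accession, []).append(r)
    for v in variants:
        applied: list[str] = []
        skipped: list[list[str]] = []
        for r in by_entry.get(v.entry_accession, []):
            pos = v.position - 1
            if pos >= len(r.sequence):
                skipped.append([r.accession, "position_out_of_range"])
            elif r.sequence[pos] != v.ref_aa:
                skipped.append([r.accession, "ref_mismatch"])
            else:
                applied.append(r.accession)
        variant_applications[v.feature_id] = {"applied": applied, "skipped": skipped}

    # ---- repository evidence sampled from the true digest ----
    evidence_sets: dict[str, EvidenceSet] = {}
    evidence_membership: dict[str, dict[str, list[str]]] = {}
    for repo in sorted(config.evidence_sampling):
        frac = config.evidence_sampling[repo]
        picks = rng.random(len(all_peptides)) < frac
        sampled = [p for p, take in zip(all_peptides, picks) if take]
        counts = {
            p: int(c)
            for p, c in zip(sampled, rng.geometric(config.experiment_count_p,
                                                   size=len(sampled)))
        }
        n_decoys = int(round(config.decoy_evidence_rate * len(sampled)))
        decoys: list[str] = []
        while len(decoys) < n_decoys:
            length = int(rng.integers(7, 26))
            decoy = "".join(rng.choice(list(letters), size=length, p=freq))
            if decoy not in index and decoy not in counts:
                counts[decoy] = int(rng.geometric(config.experiment_count_p))
                decoys.append(decoy)
        evidence_sets[repo] = EvidenceSet(
            repository=repo, counts=counts, provenance="synthetic"
        )
        evidence_membership[repo] = {"true": sampled, "decoy": decoys}

    manifest = GroundTruthManifest(
        isoforms=isoforms,
        variant_applications=variant_applications,
        planted_pairs=planted_pairs,
        expected_lost_peptides=expected_lost,
        expected_unique_peptides=frozenset(expected_unique),
        per_accession_unique=per_acc_unique,
        evidence_membership=evidence_membership,
    )
    return SyntheticDataset(
        config=config,
        records=records,
        variants=variants,
        evidence_sets=evidence_sets,
        manifest=manifest,
    )


def write_dataset(dataset: SyntheticDataset, outdir: Union[str, Path]) -> dict[str, Path]:
    """Write FASTA/TSV/JSON files consumable by the sequence_io readers."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["proteins"] = outdir / "proteins.fasta"
    write_fasta(dataset.records, paths["proteins"], header_dialect="uniprot")
    paths["variants"] = outdir / "variants.tsv"
    write_variants(dataset.variants, paths["variants"])
    for repo, ev in sorted(dataset.evidence_sets.items()):
        p = outdir / f"evidence_{repo}.tsv"
        write_evidence(ev, p)
        paths[f"evidence_{repo}"] = p
    m = dataset.manifest
    paths["manifest"] = outdir / "manifest.json"
    with open(paths["manifest"], "w") as fh:
        json.dump(
            {
                "isoforms": m.isoforms,
                "variant_applications": m.variant_applications,
                "planted_pairs": m.planted_pairs,
                "expected_lost_peptides": sorted(m.expected_lost_peptides),
                "expected_unique_peptides": sorted(m.expected_unique_peptides),
                "per_accession_unique": m.per_accession_unique,
                "evidence_membership": m.evidence_membership,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    return paths


@dataclass(frozen=True)
class CheckResult:
    name: str
    passed: bool
    detail: str


@dataclass
class RecoverySummary:
    checks: list[CheckResult]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)


def recovery_suite(config: SyntheticConfig = SyntheticConfig()) -> RecoverySummary:
    """Run the full pipeline on generated data against the manifest.

    Checks variant application accounting, cluster membership and lost
    peptides, dedup peptide preservation, unique-peptide recovery, and
    per-repository evidence fractions against a 99% binomial CI of the
    configured sampling fraction.
    """
    ds = generate(config)
    checks: list[CheckResult] = []

    expanded, log = expand_variants(ds.records, ds.variants, mode="all")
    got = {f: sorted(v) for f, v in log.applied_by_feature().items()}
    want = {
        f: sorted(d["applied"])
        for f, d in ds.manifest.variant_applications.items()
        if d["applied"]
    }
    checks.append(
        CheckResult(
            "variant_applications",
            got == want,
            f"{sum(map(len, got.values()))} applications across {len(got)} variants",
        )
    )

    clusters, _reduced = cluster_collection(ds.records)
    cluster_of = {
        acc: c.representative_accession for c in clusters for acc in c.member_accessions
    }
    pairs_ok = all(
        cluster_of[src] == cluster_of[clone]
        for src, clone, _ in ds.manifest.planted_pairs
    )
    checks.append(
        CheckResult(
            "cluster_membership", pairs_ok,
            f"{len(ds.manifest.planted_pairs)} planted pairs co-clustered",
        )
    )

    report = lost_peptides(clusters, ds.records, ds.config.digestion)
    checks.append(
        CheckResult(
            "lost_peptides",
            report.peptides == ds.manifest.expected_lost_peptides,
            f"{len(report.peptides)} lost peptides match manifest",
        )
    )

    index = digest_collection(ds.records, ds.config.digestion)
    dedup_index = digest_collection(dedup_exact(ds.records), ds.config.digestion)
    checks.append(
        CheckResult(
            "dedup_preserves_peptides",
            dedup_index.peptides == index.peptides,
            "exact-duplicate removal lost zero peptides",
        )
    )

    ureport = unicity_report(index, ds.records, exclude_ambiguous=True)
    checks.append(
        CheckResult(
            "unique_peptide_recovery",
            ureport.unique_peptide_set == ds.manifest.expected_unique_peptides,
            f"{ureport.unique_peptides} unique peptides recovered",
        )
    )

    n = len(index.peptides)
    for repo in sorted(ds.evidence_sets):
        frac = ds.config.evidence_sampling[repo]
        observed = len(index.peptides & ds.evidence_sets[repo].peptides)
        lo, hi = stats.binom.interval(0.99, n, frac)
        checks.append(
            CheckResult(
                f"evidence_fraction_{repo}",
                lo <= observed <= hi,
                f"{observed}/{n} in 99% CI [{int(lo)}, {int(hi)}] for p={frac}",
            )
        )
    return RecoverySummary(checks=checks)
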