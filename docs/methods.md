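# Methods

## Digestion model

Digestion is modelled as full proteolytic cleavage over cut sites, then
optional concatenation for missed cleavages. For `trypsin` (default) a cut
falls after every K or R except when the next residue is P (Keil rule);
`trypsin_p` cuts after every K/R. With `missed_cleavages = m`, every
concatenation of up to m+1 consecutive fully-cleaved fragments is emitted,
each with its 0-based start offset. Three deliberate edge rules:

* **No initiator-methionine cleavage.** Met-trimmed peptide variants are
  never generated; the leading Met stays where it is. This mirrors how
  database search spaces are conventionally counted and keeps the peptide
  sets of a sequence and its Met-less subfragment distinct (the source of
  N-terminal clustering losses).
* **Ambiguity codes never cleave.** B may denote N/D and Z may denote Q/E —
  neither is K/R, so the rule is vacuous but stated: only literal K/R cut.
  X/B/Z-containing peptides are flagged ambiguous and carry no mass.
* **Non-tryptic C-terminus retained.** A sequence not ending in K/R yields
  a final peptide with a non-tryptic end, which is kept; this is also how
  fragment records produce C-terminal lost peptides.

The default length filter is ≥ 6 residues: shorter peptides are rarely
detected in bottom-up MS and carry almost no sequence-specific
information. An optional maximum length supports repository-matched caps
(the major repositories' fully tryptic content historically topped out
near 66 residues, which motivates the `--max-peptide-length 66` unicity
cap).

Monoisotopic masses are sums over the pyteomics `std_aa_mass` monoisotopic
residue table (selenocysteine U = 150.95363 Da) plus one water
(18.0105646 Da), reported to 4 decimals in TSV output; ambiguous peptides
are mass-indeterminate rather than guessed.

Whether a study's counts assume `trypsin` or `trypsin_p` is often
unstated in the literature; both rules are first-class here and the choice
is recorded in every report's configuration hash.

## Variant expansion

Each single-AA variant produces at most one additional full-length
sequence per record of its entry: the record is copied, the stated
position substituted, and the copy accessioned
`<source>|<feature id>` so entry-level parsing still recovers the source
entry. A variant applies to a record only when the record's residue at the
stated (canonical-coordinate) position equals the reference residue
verbatim. Isoform coordinates are not remapped by alignment — the
verbatim check is conservative and undercounts isoform applications
relative to alignment-aware expanders (documented, not hidden: every skip
is logged with its reason). Variants never stack; the expanded collection
is always a record-superset of the input, so its digest is a
peptide-superset (a tested invariant).

Post-expansion accounting distinguishes (a) *additional* peptides — in the
expanded digest but not the base digest; (b) additional peptides
*coincident* with a second collection's digest; and (c) peptides of
variant-carrying records that already exist in the base digest — chance
within-collection coincidence, which is why naive "new peptides per
variant" counts overstate the search-space growth.

## Redundancy clustering

Two records link when their sequences are equal or one is a contiguous
substring of the other; clusters are connected components of that
relation, so a fragment contained in two unrelated longer sequences joins
them into one cluster. The representative is chosen deterministically:
longest sequence, ties broken by lexicographically smallest sequence, then
smallest accession. A configurable minimum fragment length (default 1,
i.e. no floor) gates substring merging only — some clustering pipelines
impose a floor near 11 residues, so the knob is exposed rather than
hard-coded. Substring candidates are prefiltered with a 10-mer index over
longer sequences (correctness is what is contracted; the prefilter keeps
typical collections near-linear).

Lost peptides are the member-union digest minus the representative-union
digest, each classified per contributing occurrence as N-terminal (starts
at the member's first residue), C-terminal (ends at its last) or internal.
When an occurrence is both (the member *is* the peptide), N-terminal is
reported. `dedup_exact` removes only identical-length-and-sequence
duplicates and therefore provably preserves the peptide set — the
loss-free alternative when redundancy matters but peptide content must not
change.

## Comparison and evidence annotation

Compartments are computed by exact full-string peptide identity; comparing
digests built under different digestion configurations is an error, not a
warning. "Accession unrepresented in the other collection" is
operationalized at peptide level: an accession is unrepresented iff it
contributes at least one peptide to its side's unique compartment. Gene-level
grouping of accessions is out of scope.

Evidence matching is exact, full-length, case-normalized string equality.
I and L are **not** equated and no mass tolerance is applied; anything
looser inflates evidence percentages. Percentages print with one decimal;
an exact-zero match count prints `0`. PRIDE-style sets are filtered to
peptides seen in ≥ 5 experiments (configurable) before merging;
`evidence_lookup` supports presence in at least one repository (`any`,
the default for comparison annotation) and concurrent presence in all
(`all`, the conservative three-repository intersection).

## Unicity

A peptide is sequence-unique when all its occurrences lie in one
accession; repeats within that one sequence do not break unicity (a
peptide found k times in a single protein still identifies exactly that
protein). Entry-level analysis counts, separately, peptides shared only
among one entry's isoform group; these are reported as *additional* unique
peptides and never folded into the headline percentage, because mixing the
two definitions makes percentages incomparable across collections.
X/B/Z-containing peptides can be excluded from unique counts (default)
while remaining in the totals; both modes are supported since published
tables rarely state which convention they used. U-containing peptides are
ordinary peptides and are never excluded.

## Synthetic data generator

The generator emulates the *structure* of an organism proteome collection,
not its biology: amino acids are drawn i.i.d. from Swiss-Prot background
frequencies with the combined K+R frequency rescaled to 8%, putting the
mean fully-cleaved peptide length near 12.5 residues (a realistic tryptic
length scale); sequence lengths are normal (mean 350, sd 120, floor 80)
with a leading Met. Per entry: isoforms arise by deleting one internal
15–60-residue block (guaranteeing isoform-specific junction peptides),
variants are Poisson (mean 1.5) at uniformly chosen canonical positions
with the reference residue true by construction, 30% labelled
disease-related and 0.5% being I/L swaps (the rate reported for human
variant catalogues); 15% of entries spawn an exact duplicate and 15% a
both-ends-trimmed subfragment (the planted redundancy); X/B/Z are injected
at 5·10⁻⁴ per residue. Evidence sets sample the true digest at 30%/25%/20%
(PRIDE/PeptideAtlas/GPMDB) with geometric(0.35) experiment counts — chosen
so the ≥5-experiment filter has the closed-form survival (1−p)⁴ ≈ 17.9% —
plus 2% decoy peptides absent from the digest.

What the generator does **not** emulate: real amino-acid correlation
structure, homologous families (cross-entry sequence similarity),
splice-variant coordinate annotation, PTMs, or repository FDR structure.
Passing tests therefore demonstrate correctness of the set/counting
machinery under known ground truth, not biological fidelity of any
particular published count.

The manifest predicts expected outputs from the planted structure:
duplicate/fragment co-clustering, per-variant applied/skipped targets
(verbatim rule), the lost-peptide set (family-local containment closure —
a fragment can also sit inside an isoform when it avoids the deleted
block, pulling the isoform into the cluster; cross-family containment of
independent random ≥80-mers is treated as impossible), unique peptides per
accession, and per-repository true/decoy membership.

`recovery_suite` runs the real pipeline against the manifest and checks
evidence fractions against the central 99% binomial confidence interval of
the configured sampling fraction. By construction ~1% of such checks fail
per repository under an unlucky seed; that is the statistics of the test,
not a defect.

## Numerical and formatting choices

Percentages: one decimal; exact-zero counts print `0`. Masses: ≥ 4
decimals from a ≥ 5-decimal residue table. All writers sort rows
deterministically and all generators drive a single seeded RNG, so
identical seed + config ⇒ byte-identical outputs (tested). Iteration
order of digests is by accession then offset, never dict-insertion
accidents.

## Problem sizes

The test suite exercises collections of 2–68 records plus a shared
50-entry synthetic dataset (~1000 peptides); digestion oracle checks run
1000 random sequences × 2 rules × 3 missed-cleavage settings. The
acceptance script uses a 300-entry collection (~600 records with isoforms
and clones, ~5800 peptides), an 80-entry recovery run, and the same
6000-case oracle sweep — sizes at which every planted effect (losses,
isoform-specific unique peptides, filter survival) is comfortably
non-degenerate while the whole study stays in seconds.

## Known limitations

* Variant application to isoforms undercounts relative to alignment-based
  coordinate remapping (by design; see above).
* Clustering contracts correctness at desk scale (≤ ~10⁵ sequences); the
  k-mer prefilter is not a replacement for a dedicated clustering engine
  on full UniProt releases.
* Only single-AA substitutions are expanded — no indels, multi-residue
  changes, or splice-feature expansion.
* Real repository exports must be supplied by the user as TSV; no
  downloading is performed.
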