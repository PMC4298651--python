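# peptidespace

Analysis of the **tryptic search space** of proteome sequence collections
for bottom-up mass-spectrometry proteomics.

Shotgun proteomics identifies proteins by matching spectra to the peptides
an in-silico digest of a protein database predicts. Which database you
search against therefore *is* part of the experiment: adding isoforms or
sequence variants enlarges the search space, while redundancy-removed
(UniRef100-style) collections silently destroy peptides whose cleavage
context differs between a fragment and its clustered representative.
`peptidespace` makes these effects measurable for any FASTA collection:

* **digestion** — full tryptic digest (cleavage C-terminal to K/R, with or
  without the proline exception), configurable missed cleavages, a ≥6-residue
  filter, per-peptide occurrence indexing and monoisotopic masses;
* **variant expansion** — one additional full-length sequence per annotated
  single-amino-acid variant (humsavar-style table), with a disease-only mode;
* **redundancy clustering** — 100%-identity + subfragment clustering with
  exact accounting of the tryptic peptides lost, classified as N-terminal,
  C-terminal or internal losses, plus a loss-free exact-duplicate dedup;
* **dataset comparison** — the three-compartment split of two digests
  (unique to DB1 / shared / unique to DB2) with accession-level coverage;
* **unicity** — peptides mapping to exactly one sequence (or, at entry
  level, to one entry's isoform group), with X/B/Z ambiguity handling;
* **repository evidence** — exact-match lookup of peptides against MS
  repository exports (PRIDE, PeptideAtlas, GPMDB), including the
  ≥5-experiment PRIDE filter and any/all concurrence modes;
* **synthetic data** — a seeded proteome generator with a ground-truth
  manifest, so the whole pipeline is testable without downloading a
  database release.

## Model and notation

For a collection *D* of sequences, the tryptic search space is the set
P(*D*) of peptides produced by full tryptic cleavage (after K/R, not before
P under the Keil rule; `trypsin_p` cleaves regardless), zero missed
cleavages by default, no initiator-Met trimming, length ≥ 6. Comparing two
collections splits P(D₁) ∪ P(D₂) into compartments **I** = P(D₁)∖P(D₂),
**II** = P(D₁)∩P(D₂), **III** = P(D₂)∖P(D₁). A peptide p is *unique* in
*D* when all of its occurrences lie in one sequence; unicity(*D*) =
100·|unique|/|P(*D*)|. Clustering a collection to representatives R ⊆ D
loses the peptide set P(D)∖P(R), which is non-empty exactly when a merged
fragment's terminal cleavage context differs from its representative's.

## Worked example

Generate a 40-entry synthetic proteome (isoforms, variants, planted
duplicates/fragments, repository evidence) and analyse it:

```
$ peptidespace simulate --seed 7 --n-entries 40 --out data
$ peptidespace unicity data/proteins.fasta --entry-level --out unicity
INFO 497/730 unique (68.1%)
$ cat unicity/unicity.tsv
dataset  total_peptides  unique_peptides  unicity_percent  isoform_specific_unique  entry_level_additional_unique  excluded_ambiguous
proteins 730             497              68.1             21                       177                            4
```

Of 730 tryptic peptides, 497 (68.1%) map to exactly one sequence; 21 of
those are isoform-specific (they exist only because isoforms are in the
collection), 177 more would count as unique at entry level (shared only
within one entry's isoform group — reported separately, never folded into
the headline percent), and 4 otherwise-unique peptides were excluded for
containing X/B/Z.

```
$ peptidespace cluster data/proteins.fasta --out clust
INFO 68 records -> 63 clusters; 6 lost peptides
$ head -3 clust/lost_peptides.tsv
peptide    member_accession  terminal_class
ADAIIWTSR  T70021            n_terminal
AEGGPR     T70014            n_terminal
```

Clustering removed 5 redundant records and destroyed 6 peptides — each one
listed with the member it came from and where on that member it sat.

```
$ peptidespace compare data/proteins.fasta data/proteins.fasta \
      --evidence PRIDE data/evidence_PRIDE.tsv --min-experiments 5 --out cmp
$ cat cmp/comparison.tsv
dataset   peptides  evidence_count  evidence_percent
proteins  0         0               0
proteins  0         0               0
Com.      730       49              6.7
```

A collection compared against itself has empty unique compartments (a
structural zero); 6.7% of the shared peptides survive the ≥5-experiment
PRIDE evidence filter.

All subcommands (`digest`, `expand`, `cluster`, `compare`, `unicity`,
`evidence`, `simulate`) accept `--rule trypsin|trypsin_p`,
`--min-length`, `--missed-cleavages`, and a `--config key=value` file;
every report starts with a comment line carrying the tool version and a
configuration hash so derived datasets keep their provenance.

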