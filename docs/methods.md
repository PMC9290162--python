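# Methods

This note documents the models, parameters and design choices behind the
pipeline, in the order the data flow through it, followed by what the
simulator does and does not emulate, and known limitations.

## Panel model and coordinates

A panel bundles everything assay-specific: primer pair, candidate isoform
references, the catalogue of known resistance mutations, and thresholds.
Mutations are expressed in protein coordinates (ABL1 numbering for the
shipped BCR-ABL1 panel); each isoform carries two metadata fields,
`cds_start` (1-based position of the first base of the first complete codon)
and `codon_offset` (the amino-acid number of that codon), so codon *c* maps
to nucleotides `cds_start + 3(c − codon_offset) .. +2`. Gene structure is
therefore configuration, never code. At load time the panel is
self-checked: every catalogued mutation's reference codon must translate to
its stated wild-type amino acid on every isoform that spans it, which
catches off-by-one numbering immediately.

All user-facing coordinates are 1-based inclusive; internal arrays are
0-based half-open.

The shipped demo references are synthetic stand-ins (random non-stop codons
with the fifteen catalogued wild-type codons fixed at their numbered
positions, each alternate reachable by one substitution). They are not the
true fusion transcript; they exist so the package is fully exercisable with
no external data. The two isoforms differ by a 75-nt 5′ block, mirroring the
exon-usage difference between the common fusion isoforms.

## Primer filtering

Primer search is anchored: only the terminal `len(primer)` bases of a read
are compared, by Hamming distance, with `max_primer_mismatches = 2` by
default; `N` always counts as a mismatch. Both layouts are tried (forward,
then the reverse complement of the read) and kept reads are oriented to the
reference strand with both primer spans trimmed, so primer-synthesis errors
can never appear as variant sites. Anchored matching is deterministic and
sufficient for high-accuracy consensus reads; it deliberately does not find
primers in the middle of a read (no concatemer/chimera rescue). Reads whose
trimmed insert would be empty are rejected with their own reason
(`empty_after_trim`) rather than being forced into one of the primer-failure
categories.

## Isoform assignment

A seeded subsample (default cap 500 reads, drawn after a seeded shuffle so
the choice is reproducible and order-independent) is scored against every
candidate isoform; each read votes for its best-scoring isoform and the
majority wins, ties resolved by panel order and flagged in the run summary.
Minority-isoform reads are *not* discarded afterwards — they align to the
chosen reference with a block gap and still contribute codon observations
wherever their alignment is unambiguous.

## Alignment and pileup

Alignment is semi-global with affine gaps: the whole read must align,
reference positions outside the read's span are free. Default scores:
match +2, mismatch −4, gap open −6 (charged on the first gapped base),
gap extend −1, so a gap of length *g* costs 6 + (g−1). Traceback is
deterministic with ties broken match/mismatch > deletion > insertion.

Two backends share one semantics. The definitional aligner is an exact
numpy-vectorized Gotoh DP (its single-pass gap recurrence requires
`gap_open ≤ gap_extend ≤ 0`, which the validator enforces). The pipeline
default is an edit-distance backend (edlib, infix mode) whose path is
converted to the same observation encoding and re-scored under the affine
scheme: for low-error consensus reads the paths coincide with the DP paths
up to gap placement inside homopolymers, at orders-of-magnitude lower cost.
The tests pin the DP against an independently written exhaustive top-down
oracle and pin the fast backend against the DP on substitution-only reads;
on arbitrary sequence pairs the fast backend's affine score can only be ≤
the DP optimum.

Pileup semantics: per position, counts of A/C/G/T/N/deletion. Deletions
count toward coverage (a read spanning a deleted base did observe the
locus); `N` does not. Insertions go to a side table and never become
substitution calls. Alignments spanning < 50 % of the reference are flagged
partial — likely truncated or chimeric molecules — and excluded from pileup
and phasing (counted in the run summary; threshold configurable).

## Coverage QC

Every position of the assigned reference (the whole primer-trimmed span)
must reach `min_coverage = 100` reads. Failure is a controlled abort: the
sample is stored with status `qc_failed`, the report carries a failure
banner, and *no* mutation is reported negative — an absence claim at an
under-covered site would be clinically unsafe. The CLI signals this state
with exit code 3.

## Variant calling and classification

The de novo scan emits every (position, alternate base) with
`alt_count ≥ min_alt_reads` (default 3) and `VAF ≥ positive_cutoff`
(nucleotide-level counts; VAF = alt / coverage). The amino-acid label is
derived when the site is coding and the change non-synonymous, substituting
the alternate into the reference codon.

Catalogued mutations are called per read at codon level: a read supports
the mutation when its three aligned codon bases — no gap, no `N` — translate
to the alternate amino acid. The VAF denominator is the number of reads
whose codon translates to the wild-type amino acid *or any catalogued
alternate at that codon*; codons translating to an uncatalogued amino acid
are reported as `other_reads` and excluded. Rationale: in high-accuracy
amplicon data such observations are almost always sequencing-error
artifacts, and excluding them makes the estimator unbiased to first order
in the per-base error rate — with an error rate *e* per base, roughly 2.3·*e*
of true carrier codons translate to a third amino acid, which would
otherwise deflate a 97 % VAF by ~0.7 percentage points. It also makes the
calling denominator consistent with the informative-read denominator used in
phasing. Including same-codon catalogued alternates in the denominator
(rather than only ref-or-this-alt reads) keeps multi-allelic codons like
F359 (I/V/C all catalogued) on a common, additive scale.

Classification is monotone in VAF with fixed boundary semantics:
`VAF < 0.005` → negative; `0.005 ≤ VAF ≤ 0.01` → positive;
`VAF > 0.01` → clinically reportable. The positive cutoff is inclusive
(frequencies *down to* 0.5 % are reliably detectable); the clinical cutoff
is strict (*above* 1 %). Both are panel configuration.

At the default error model the per-read false-support rate for a specific
codon change is ≈ e/3 ≈ 0.1 %, rising to ≈ e ≈ 0.3 % for degenerate targets
such as M→I where every third-position change of ATG yields isoleucine.
This floor sits comfortably below the 0.5 % cutoff at the assay's intended
coverage (≥ 10⁴ reads) but makes low-coverage runs (< ~2,000 reads)
vulnerable to sporadic borderline positives — one reason the coverage QC
gate exists.

## Clonal phasing

Full-length reads make phasing exact, so no statistical inference is used:
reads are genotyped over the sample's positive mutation sites (alt / ref /
missing, where "missing" covers gaps, `N` and third amino acids), reads with
any missing site are dropped (but counted), and the rest are grouped by
exact mutation set. By construction the clone fractions over informative
reads satisfy an exact identity: the fractions of clones containing mutation
*m* sum to *m*'s informative-read VAF (checked to 1e−9 in the tests).

Categorical co-occurrence statements need an operational noise floor:
counts below `max(2 reads, 0.2 % of informative reads)` are treated as
zero, guarding against chimeric molecules and residual errors. Then, for an
ordered pair (a, b): `same_clone_only` when b never appears without a but
true double mutants exist; `exclusive` when the double-mutant count itself
is below the floor — including the degenerate case where both effective
counts vanish, which carries no co-occurrence evidence; `mixed` otherwise.

## Results store, reports, concordance

The store is append-only JSON Lines, one canonical record per line;
re-analysis appends, never overwrites, and identical duplicates are stored
(with a warning) under a new record id. Reports list every panel mutation
with VAF as a percentage to one decimal, the QC block, the clone table as a
text bar diagram, and the pipeline version plus a content hash of the panel
— enough to reproduce any reported number.

Concordance compares a frequency-free reference call set (Sanger-style)
with the pipeline's per sample: labels match exactly, except that a bare
codon label (e.g. `E255`, alternate unresolved) matches any label sharing
its wild-type amino acid and codon. Counted are: reference-method mutations
(and how many the pipeline missed), pipeline-only mutations at full
sensitivity and above the clinical cutoff (strict >), and per-sample classes
(both negative / full agreement / pipeline-found-more / other). The shipped
39-sample fixture transcribes a published validation cohort; one source
figure labels the rare codon-247 mutation "K257R" while the tables say
"K247R" — the fixture uses K247R.

## Simulator

The generator emulates one run of a multi-clone sample. Each clone is a set
of substitutions — catalogued labels resolved to the minimal nucleotide
change reaching the alternate amino acid (ties broken alphabetically by
codon) or raw (position, base) pairs — at a stated population fraction.
Reads get iid per-base substitution errors (default 0.003, uniform over the
three alternates) and indel errors (default 0.001, deletion or single-base
insertion with equal probability), then primers, then reverse-complementation
with probability 0.5. Off-target reads are primer-free uniform-random
sequences. Error-rate defaults are on the scale of circular-consensus
accuracy; they are deliberately pessimistic enough to exercise the
thresholds.

Clone membership uses an exact largest-remainder allocation of `n_reads` to
the fractions followed by a seeded shuffle — a stratified draw honoring the
stated fractions exactly. This removes multinomial noise from the *design*
(the detection-floor measurement at the 0.5 % cutoff would otherwise be a
coin flip at exactly 50/10,000 reads) while orientation and errors remain
iid. A fixed seed reproduces byte-identical FASTQ output.

The truth record written alongside the reads carries per-read clone
identity and each mutation's exact expected VAF, so tests compare pipeline
output against declared truth, never against generator internals.

What the simulator does **not** model: quality-score structure, homopolymer
or context-dependent error bias, PCR chimeras and amplification bias,
primer-region errors, or subread-to-consensus behavior. Passing tests
therefore demonstrate the pipeline's statistical and structural correctness
on idealized-error reads, not robustness to instrument-specific artifacts —
the coverage QC and noise floors address those operationally.

## Problem sizes and numerics

Simulation-backed checks run at 10,000 reads per sample (the assay's
working coverage) for detection-limit, VAF-recovery and phasing tests, with
20 seeded replicates where a frequency-of-success claim is made; structural
identities (clone-fraction/VAF) are asserted to 1e−9; the estimator-bias
property is checked at zero error rate, since with noise any counting
estimator carries the ≈ 0.1 % false-support floor described above, which is
a property of the error model, not the estimator. The aligner oracle runs
on 200 random pairs of length ≤ 20 where exhaustive search is cheap.

## Known limitations

* Substitutions only: no indel or structural-variant calling (insertions
  are tabulated, deletions only affect denominators), no multi-nucleotide
  variants, and compound changes within one codon are reported only through
  the catalogued-alternate labels.
* Single-sample scope: no longitudinal clone tracking, no phylogeny of
  clones.
* Isoform candidates come from the panel; there is no de novo isoform
  discovery.
* VAF confidence intervals are not reported; at the assay's coverage the
  binomial standard error at the clinical cutoff is ≈ 0.1 %, an order of
  magnitude below the decision boundaries.
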