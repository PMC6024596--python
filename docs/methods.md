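# Methods

## Problem and model

The package answers two questions about a tight phage genus (the model
system is the PB1-like *Pseudomonas* phages: ~66 kbp circularly
permuted genomes, ~90 CDS, >99% intragenus nucleotide identity):

1. *Which reference genes are genus signatures?* A gene is a usable
   signature ("informative") only if no genome outside the genus
   resembles it as much as the genus's own most distant member does.
2. *Does a virome contain the phage, and can a complete genome be
   recovered from its assembly?* Detection is summarized in a genome
   atlas; recovery is gated by a read-depth completeness filter.

## Alignment core

All similarity is exact affine-gap Smith–Waterman (no heuristic
seeding): the corpora are single genomes and contigs, so O(nm) is
affordable and scores are deterministic. Protein queries are searched
against all six conceptual translations of a nucleotide subject
("blastx-style" with the protein as query; the package fixes this
direction and maps subject coordinates back to nucleotide space).

Statistics use the Karlin–Altschul form S′ = (λS − ln K)/ln 2 and
E = m·n·2^(−S′) with fixed constants — gapped BLOSUM62 λ = 0.267,
K = 0.041; nucleotide (match/mismatch 2/−3, gaps 5/2) λ = 0.625,
K = 0.41 — rather than per-search estimation. The search space m·n is
raw query length × total subject length with no edge correction; when a
sample is split over several contigs, n is the summed contig length so
the statistics are invariant to fragmentation. Gap costs follow the
BLAST convention (a k-long gap costs open + k·extend, so 11/1 charges
12 for the first gapped column). Among co-optimal alignments the
aligner's canonical traceback is reported; it is deterministic for
fixed inputs.

## Informativity

For each reference CDS (translated, trailing stop trimmed):

* `floor` = bitscore of its best hit in the most distant intragenus
  relative, where "most distant" minimizes the mean best-hit bitscore
  over all genes (ties to smallest genome id);
* `best_out` = best bitscore over all outgroup genomes;
* uninformative ⇔ `best_out ≥ (1 − ε)·floor`, with ε = 0.05 by
  default. ε operationalizes "on par": the strict reading is ε = 0, and
  raising ε can only move labels toward uninformative (monotone).

Floor and outgroup scores are plain bitscores of the best local hit
(0 when no positive-scoring alignment exists); they are deliberately
not gated on E-value, so short genes are compared on the same footing
as long ones. Optionally (`require_intragenus_presence`, default on) a
gene must also be detected at E ≤ 1e−5 in every *close* intragenus
genome — the strain cluster, excluding the floor relative itself, which
only calibrates the similarity floor.

## Genome atlas

Cell(gene, sample) = (query coverage % + identity %) / 2 of the single
best (max-bitscore) hit of the gene in the sample's contigs at
E ≤ 1e−5; no merging of multiple HSPs (a documented limitation: a gene
split across contigs scores by its best piece). Cells without a hit are
missing, not zero — rendered grey — because absence of evidence is
displayed differently from weak similarity. Rows keep reference gene
order; a bar above the heatmap shows per-sample read counts (data
volume), and the exact matrix is written as TSV with `NA` for missing.

## Genome recovery and QC

* Length filter: contigs ≥ 20,000 nt.
* Screen: keep contigs with ≥ 1 translated gene hit at E strictly
  < 1e−5 (the boundary value is excluded, matching the printed
  inequality).
* Read mapping: exact-seed (k = 21, three read offsets) + full-length
  ungapped comparison, accepting a mate at its best position when ≥ 90%
  identical; ties to the lowest coordinate; circular genomes allow
  placements across the origin. This is a depth profiler for
  near-identical references, not a general-purpose aligner. Depth
  counts each mate independently (read depth); a `count_fragments` flag
  counts once per pair instead.
* Completeness filter: reject when any maximal run of ≥ 100 bp has
  depth < 5. Raising `min_depth` or lowering `min_len` is monotone
  (never converts rejected to accepted).
* Frame adjustment: the reference is located in the doubled candidate
  sequence on both strands by edit-distance alignment; the candidate is
  reverse-complemented if needed and rotated so the match starts at
  coordinate 0. Idempotent. Candidates whose best orientation exceeds
  0.4 edit-distance per reference base are rejected: genuine relatives
  sit ≤ 0.3, unrelated random DNA near 0.49.
* Annotation projection: each reference CDS is located in the
  recovered genome by full-length infix alignment; the located copy is
  scored with the nucleotide scheme (affine costs recomputed from the
  alignment path) and called *absent* at E > 1e−5, *disrupted* on a net
  indel ≢ 0 (mod 3) (frameshift), any single indel ≥ 30 nt ("large
  indel" — the threshold is configurable since only the category is
  standard), or a premature in-frame stop, else *intact*.
* Pairwise differences: global end-free comparison; the count is
  mismatched plus gapped columns inside the co-linear core, with
  terminal overhang lengths reported separately. Percent identity uses
  identical columns over all alignment columns (terminal gaps
  included), diagonal 100.

Whole-genome pairwise operations run on exact unit-cost alignment
(edlib), which is the appropriate tool at >99% identity; affine-gap DP
over 66 kb × 66 kb is neither needed nor affordable.

## Phylogenetics

Distances: p = differing ungapped columns / ungapped columns (pairwise
deletion — robust when a few genomes have small deletions), corrected
by Jukes–Cantor d = −(3/4)·ln(1 − (4/3)p); p ≥ 0.75 raises a
saturation error. Trees: Saitou–Nei neighbor joining with the
Studier–Keppler Q-criterion, deterministic tie-breaks by smallest label
pair, negative branch estimates clamped to 0; exact on additive
matrices (tested against topology enumeration + least squares, and
cross-checked against an independent library implementation).
Bootstrap: columns resampled with replacement, default 100 replicates,
support = % of replicate trees containing the original internal
bipartition; an alignment of identical sequences degenerates to an
unresolved star with no supports. Multiple alignment of genus genomes
uses reference-anchored column projection (each genome aligned pairwise
to the reference; insertions relative to the reference dropped,
deletions gapped): at >99% identity this is column-accurate for
distance purposes and avoids progressive whole-genome alignment.

## In-silico PCR

A primer binds where it (or its reverse complement on the minus
strand) matches with ≤ `max_mismatches` mismatches and the 3′-terminal
3 nt exactly — the polymerase-extension constraint, configurable.
Amplicons are all (+ forward, − reverse) site combinations with the
forward 5′ end upstream of the reverse 5′ end and product length
between the summed primer lengths and `max_product` (5 kb default).
Circular templates are scanned across the origin. Published reverse
primers for this genus are printed 3′→5′ in places; the parser's
`reverse_orientation` switch covers both readings, defaulting to the
standard 5′→3′ convention (the packaged fixture's own tests build
templates under that convention). Tm is the Wallace rule
2(A+T) + 4(G+C), adequate for 16–18-mers; nearest-neighbor
thermodynamics is out of scope.

## Synthetic data: what it emulates, and what not

The generator is a pure function of (config, seed). It produces:

* a reference of `n_genes` (default 90) stop-free ATG…stop CDS of
  ~650 ± 100 nt with ~80 nt spacers (≈ 66 kbp total), flagged circular
  (circularly permuted phage genome);
* relatives by i.i.d. per-site Jukes–Cantor substitutions at the
  configured divergences (defaults: five close members at 0.5–5% and
  one distant at 25% — the intragenus floor), with an optional
  `preserve_genes` mode that redraws stop-creating substitutions and
  confines indels to intergenic DNA;
* outgroups that are i.i.d. random sequence except for designated
  shared genes evolved at a configurable divergence (default 2%) — the
  planted uninformative set;
* paired-end viromes: uniform fragment positions (wrapping the
  origin), normal insert 400 ± 40, 2 × 150 nt reads, substitution-only
  errors at 0.5% with constant Q30, expected depth equal to the
  configured abundance (default 30×, within the study's 15–220×
  range);
* coverage dropouts, emulated by replacing the window with unrelated
  sequence in the genome reads are drawn from: reads internal to the
  window then fail to map back, while boundary-spanning reads still
  map — the signature of an assembled region unsupported by its own
  sample. (Excluding reads or fragments overlapping the window instead
  would shadow the flanks by a read/insert length and make the
  99-vs-150 bp window-length boundary of the QC filter untestable.)

Because substitutions follow the same uniform model the Jukes–Cantor
correction assumes, distance and topology recovery tests are genuine
parameter-recovery tests. The generator does *not* emulate realistic
error profiles, quality-score variation, chimeras, strain mixtures,
repeat structure or assembly artifacts — so passing tests demonstrate
the correctness of the algorithms under the stated statistical
assumptions, not robustness to every pathology of real viromes.

## Problem sizes in tests and the acceptance script

Alignment-heavy stages (informativity, atlas) run on genera of 8–12
genes of ~240 nt — small enough for exhaustive cross-checking while
preserving the score geometry (close relatives ≫ floor ≫ chance).
Mapping, QC, frame adjustment and whole-genome comparisons run on
full-size ~66 kbp genomes. QC behavior is probed at 15× (the minimum
accepted coverage) for plain acceptance, and the 150 bp vs 99 bp
window-length boundary at 115× (the median coverage of the accepted
study genomes), where the filter's decision reflects the window length
rather than sampling noise. The brute-force alignment oracle enumerates
all substring pairs at ≤ 12 residues; NJ exactness is checked against
full topology enumeration at 4–6 taxa.

## Known limitations

* Atlas cells come from the single best hit; genes fragmented across
  contigs under-score.
* The read mapper is ungapped; indel-bearing reads near true variants
  are dropped, slightly depressing depth near indels (irrelevant at the
  ≥ 90%-identity, substitution-only regime it serves).
* Karlin–Altschul constants are fixed, not estimated per search;
  E-values are reproducible but approximate in absolute terms.
* The difference count's treatment of terminal overhangs (excluded,
  reported separately) is one of several defensible conventions for
  "pairwise differences" between genomes of unequal length.
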