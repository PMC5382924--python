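# Methods

## Scope and model

`crisprleader` reconstructs, as a tested pipeline, a comparative analysis of
type II-A CRISPR loci. A locus qualifies as type II-A when a genome carries
all four signature cas genes — *cas9* (historically *csn1*), *cas1*, *cas2*
and *csn2* — in one compact operon. The orientation of the cas genes gives
the transcription direction of the adjacent leader-repeat unit, so the
leader and the CRISPR array are searched for in a window (default 400 nt)
immediately downstream of *csn2* in that direction.

Within the window the pipeline locates the repeat-spacer array, takes the
**first repeat verbatim from the genome** (not a database consensus — the
genomic first repeat is what spacer acquisition duplicates), and defines the
leader as everything between the window start and that repeat. The analysis
unit is the last 20 leader nucleotides plus the first repeat. Each locus is
assigned to one of three 3′-leader-end motif groups:

* **Group 1** — leader ends `ATTTGAG`;
* **Group 2** — leader ends `CTRCGAG` (IUPAC `R` = A or G);
* **Group 3** — only a short terminal `CG` is conserved, preceded by a
  partially conserved A-rich stretch (reported in the profile but not used
  for classification).

Matching precedence is Group 1 > Group 2 > Group 3, with a configurable
mismatch tolerance (default 0; the degenerate `R` never counts as a
mismatch). Because the published group membership was derived from Cas1
tree clades rather than from the motif directly, a second **clade mode** is
provided: each locus inherits the majority motif-group of its Cas1-tree
clade. Motif mode is the default because it is parameter-free.

## Array detection

The detector is a seed-and-extend tandem-repeat scanner:

1. index all k-mers of the window (k = 8);
2. k-mers recurring with gaps inside the CRISPR period range
   (repeat 24–50 nt + spacer 20–60 nt ⇒ period 44–110 nt) nucleate a
   candidate chain of copies;
3. repeat boundaries grow column-by-column while the column's majority base
   fraction is ≥ `boundary_consensus` (default 0.75) and the unit stays
   ≤ 50 nt;
4. copies whose agreement with the column consensus falls below
   `copy_identity` (default 0.75) are expelled and the boundaries
   re-extended. This guards against a chance seed k-mer in the A/T-rich
   leader "free-riding" on the majority vote of four or more true copies,
   which would otherwise shift the detected first repeat into the leader;
5. overlapping candidates merge (more copies > longer unit > smaller
   start); arrays need ≥ 2 copies and in-bounds spacers. Candidate repeats
   containing `N` are rejected and the locus flagged.

A brute-force reference (`crisprleader.reference`) enumerates all maximal
exact periodic substring triples (offset, unit, period) and serves as the
detector's oracle in tests. With ≤ 3 copies the 0.75 majority rule demands
unanimity, so detector and oracle coincide exactly on unmutated arrays;
with ≥ 4 copies the majority rule is deliberately more permissive than
exact periodicity (3/4 agreement extends a boundary), which is what lets
real, slightly degenerate repeats be recovered. Boundary accuracy improves
with copy number: with 12-copy arrays and 2% per-copy substitution the
planted 36-nt unit is recovered in ≥ 95% of seeded trials; with very few
copies a single chance-agreement column adjacent to the array can extend
the boundary by one base — an ambiguity intrinsic to any purely periodic
definition of a repeat, and the reason repeat calls on real data deserve
inspection.

## Alignment and trees

Junction sequences are ≤ ~60 nt, so multiple alignment is done in-repo: a
Gotoh affine-gap global aligner (gap of length *g* costs
`gap_open + (g−1)·gap_extend`; DNA defaults +2/−1/−4/−1; deterministic
traceback diagonal > up > left) and a progressive profile aligner guided by
UPGMA clustering of pairwise identity distances. Exact column-level
optimality of the multiple alignment is not claimed; tests assert lossless
ungapping and that the sum-of-pairs score is at least that of the worst
center-star alignment.

Cas proteins (up to ~1,400 aa) are compared alignment-free:
`d(i,j) = 1 − |Ki ∩ Kj| / min(|Ki|, |Kj|)` over sets of distinct k-mers
(k = 4 for proteins, 6 for DNA). Trees are built by classical neighbor
joining (Saitou–Nei), with deterministic tie-breaking by leaf-label pair
and negative branch lengths clamped to zero with the deficit moved to the
sibling edge. NJ exactly recovers additive matrices, which is the tested
guarantee; likelihood-based inference is intentionally out of scope because
the downstream claims consumed here are clade-membership claims, not
branch-length claims.

Trees are midpoint-rooted and cut into k clades (default 4) by repeatedly
splitting the cluster whose longest **internal** connecting edge is longest;
leaf edges are only cut when a cluster has no internal split left (e.g.
k = n). Outlier leaves therefore stay inside their clade and surface in the
concordance report instead of becoming singleton clades. Concordance
between clades and motif groups is reported as purity and adjusted Rand
index with the full contingency table.

## Conservation profiles

The logo computation: per-column symbol counts over non-gap characters
(optional pseudocount), frequencies, gap fraction, and information content
`R = log2(4) − H − e(n)` in bits, where `H` is the column Shannon entropy
and `e(n) = 3 / (2·ln2·n)` is the small-sample correction (off by default,
so analytic column values are exact; switch it on for reports from few
sequences). The IUPAC consensus takes, per column, the smallest degenerate
symbol whose base set reaches the cumulative frequency threshold (default
0.9), adding bases in descending frequency, ties alphabetical.

## Synthetic data

The generator emulates the surveyed dataset so the whole pipeline is
testable offline:

* 87:55:25 group proportions (deterministic largest-remainder allocation),
  n_loci = 30 by default, 167 for study-scale runs;
* per locus, a cas9–cas1–cas2–csn2 operon (back-translated CDSs with
  translations attached), a 150-nt leader at 70% A/T ending in the group
  motif, then 4 copies of a 36-nt repeat (`GTTT…AAAC`, first base G, last
  base C) separated by 30-nt spacers; loci land on the reverse strand with
  probability 0.5; decoy tandem repeats with a period far below the CRISPR
  range are inserted upstream in a quarter of loci;
* proteins are random sequences with fixed group- and subgroup-signature
  segments — **not** homologs of real Cas proteins — sufficient for k-mer
  distances to cluster loci by group. Group 1 contains an "ancestral"
  subgroup 1a carrying a long (320 aa) Csn2 and a derived 1b with the short
  (218–230 aa) form, so Cas1/Csn2 trees segregate into four branches and
  the mean Csn2 length per clade reproduces the long/short dichotomy;
* genus labels are drawn from per-group pools (42 genera for Group 1, 5 for
  Group 2, 7 for Group 3, 50 distinct overall, with overlap between
  groups);
* all mutation rates default to 0, so the planted truth is exact; the
  motif, repeat copies, and proteins can be independently degraded.

One generator subtlety is **boundary identifiability**: if the characters
flanking the planted repeat copies (leader end, spacer ends, downstream
pad) agreed by chance, the locus's true repeat — under any periodic-array
definition, including the brute-force oracle — would be wider than the
planted unit, and the truth table would contradict itself. Flanking
characters are therefore resampled until no symbol holds a majority in a
boundary-adjacent column. This pins the planted boundary as the maximal
one; it does not make detection easier than the stated conditions.

What the generator does **not** emulate: real Cas homology and
within-group sequence divergence structure, pseudogenes and annotation
noise, multiple loci per contig, N runs, spacer-protospacer relationships,
and the real-world exceptions the survey reports (repeat-length outliers,
loci lacking 5′ `GTTT`). Passing tests therefore demonstrate correctness of
the machinery under the stated conditions, not detection performance on
real genomes.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open on the forward strand throughout;
  1-based inclusive conversion happens only at I/O boundaries.
* Windows truncated by a contig edge are processed with a flag; zero-length
  windows, empty leaders, duplicated cas roles and 2-vs-2 strand ties are
  dropped with per-locus reason codes, and dropped + reported always equals
  the number of assembled operons.
* `N` mismatches every base except `N`; candidate repeats containing `N`
  are rejected.
* Floating-point ties in alignment tracebacks, NJ Q-criterion, clade
  cutting and consensus calls are all broken deterministically, so a run is
  byte-reproducible from its inputs and seed.

## Problem sizes used in validation

The self-contained validation uses 30-locus datasets for end-to-end checks
and orientation invariance, a 167-locus dataset for study-scale statistics,
100 windows for detector/oracle equivalence, 100 random 5–8-leaf additive
matrices for NJ recovery, 200 12-copy arrays for boundary recovery, and
exhaustive alignment enumeration for string pairs up to length 8.

## Known limitations

* Homology-based locus discovery (protein-profile or BLAST search) is out
  of scope: annotation names drive gene finding, so unannotated or
  renamed cas genes are invisible.
* The detector reports what is periodic in the window; repeats longer than
  50 nt, spacers outside 20–60 nt, or arrays with fewer than 2 copies in
  the window are not found.
* Tree shapes are NJ-on-k-mer approximations; only clade membership, not
  topology detail or branch support, should be interpreted.
* Classifying real junction datasets at tolerance 0 labels any motif
  variant `unclassified`; clade mode (or a tolerance ≥ 1) is the
  appropriate setting for diverged loci.
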