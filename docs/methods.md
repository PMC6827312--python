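# Methods

This note documents the models, parameters, and numerical choices behind
`ssnfam`, and what the synthetic fixtures do and do not demonstrate.

## Pairwise statistics

Edges of the similarity network come from optimal affine-gap local alignments
under BLOSUM62 with the BLAST gap convention: a gap of length L costs
`11 + L` (gap open 11, extend 1). The aligner is biotite's optimal
Smith–Waterman (`gap_penalty=(-12, -1)` reproduces the convention exactly);
its scores are verified in the test suite against an independent brute-force
Gotoh dynamic program on hundreds of short random pairs.

Raw scores `S` are converted with the standard gapped Karlin–Altschul
parameters for BLOSUM62/11/1, `λ = 0.267`, `K = 0.041`:

    bits = (λ·S − ln K) / ln 2,      E = m · n · 2^(−bits)

where `m` is the query length and `n` the total residue count of the dataset.
Two deliberate simplifications relative to blastp defaults: no
composition-based score adjustment, and raw rather than effective search-space
lengths. Both shift E-values slightly; on well-separated families the induced
component structure is identical to a real BLAST+ run (checked in the suite
against `blastp -outfmt 6`). E-values are floored at 1e-180 so log-binning over
the full threshold grid is always defined. When importing BLAST tabular files,
directional rows and multiple HSPs per pair collapse to the minimum-E entry —
the permissive convention for undirected edges; E-values printed as `0.0` take
the floor.

## Networks and the threshold scan

The SSN at threshold `t` contains every sequence as a node (isolated nodes
retained) and an edge for every pair with `E ≤ t`. The inclusive comparison
means a hit exactly at a grid value is kept at that grid point; off-grid the
choice is immaterial. The default grid is 1e-5 … 1e-120 in 5-log steps
(24 thresholds).

Components are computed with a union-find structure (validated against a BFS
oracle); the scan walks the grid strictest-first so edges are only ever added,
making the whole 24-threshold scan a single pass over the sorted edge list.
Because edge sets are nested across thresholds, each component at a stricter
threshold lies inside exactly one component at a looser threshold; the scan
records these parent links and emits them as a long-format table
(threshold, cluster, size, parent).

Metanode contraction finds groups mutually connected at `E ≤ 1e-85` by an
explicit depth-first search, names each group after its smallest member id,
and keeps the minimum E per contracted edge. Contraction cannot change the
component structure at the display threshold (quotient property, tested on
random graphs).

Cluster ids everywhere are deterministic: descending size, ties broken by the
lexicographically smallest member. All exports are byte-reproducible.

## Subfamily calling

A component qualifies as a subfamily iff it has at least `min_size = 20`
members and at least `min_distinct = 2` distinct non-empty values at the
`class` rank. "Diversity above the class level" is not formalizable from
lineage strings alone, so the rank and count are configurable, and a per-cluster
override waives the diversity requirement (robust single-taxon clusters exist;
the size floor is never waived). Sequences in failing clusters are reported as
nonclassified, never force-merged.

Numbering is descending-size with the smallest-member tiebreak. An explicit
user-supplied ordering is accepted because observed subfamily numberings in
curated databases are not always a pure size ordering. Representative sampling
is a seeded uniform draw of 30 members (all members if fewer).

## Profile HMMs

The library models are simplified Plan7-style profiles:

- **Architecture.** Match/insert/delete columns with begin/end states and
  self-looping N/C flanks that emit the background (loop probability 0.9).
  The model is glocal: a sequence must traverse the whole column chain
  (deletes allowed), with flanks absorbing overhangs. All nine M/I/D
  transitions are estimated (Plan7's two forbidden ones are allowed here for
  simplicity of counting); the last column can only exit to the end state.
- **Estimation.** Columns with ≤ 50% gaps become match states. Match emissions
  are `(counts + w·background) / (n + w)` with `w = 1` by default; transitions
  are counted from each row's implied state path with a unit pseudocount.
  Insert runs outside the first/last match column belong to the flanks and are
  not counted. The background is the Robinson–Robinson composition.
- **Scoring.** A log-space forward algorithm (numba kernel) returns the bit
  score `log2 P(seq|model)/P(seq|background)`; insert and flank emissions
  cancel against the null, so only match emissions and transitions contribute.
  A Viterbi kernel exists for diagnostics; forward ≥ Viterbi is asserted in
  tests.
- **Calibration.** Each model scores 200 random background sequences of its
  own match length; a Gumbel is fitted by the method of moments
  (`β = σ·√6/π`, `μ = mean − γβ`) with the scale floored at 0.5 bits. The
  floor matters for the degenerate case of the flat remainder model, whose
  null scores are constant: without it, any score a hair above the null would
  claim unbounded significance. `E = search_space · P(score ≥ x)`; the tail
  probability is computed in log10 space (`log sf → −z` for large `z`), and
  **all E-value comparisons are done in log10 space** because genuine hits sit
  hundreds of bits above the null, far below double-precision underflow. The
  displayed E-value field is floored at 1e-300.
- **Remainder model.** When the nonclassified set is empty, the "+1" model is
  a flat background emitter at the median subfamily model length; it scores
  ~0 bits for everything and never outranks a real model, but keeps the
  library structurally S+1.

The two-condition rule reads "second best at least 1e10-fold greater" as
`E₂ ≥ E₁ · 1e10` (less significant); both the ceiling and the fold are
configurable, and precision/recall tables vary the ceiling on a grid while
keeping the fold fixed. A sequence whose best-scoring model is the remainder
yields no prediction. In the evaluation, a wrong prediction counts once, as a
false positive (not additionally as a false negative); precision at zero
predictions is defined as 1 and flagged.

This is deliberately not a HMMER reimplementation: no entropy weighting,
Dirichlet mixtures, multihit mode, or analytic calibration. The workflow only
needs correctly ranked E-values. A pyhmmer backend
(`ssnfam.hmmer_backend`) builds real Plan7 models from the same training sets
and is used in the test suite to confirm best-model agreement.

## Synthetic families

The generator draws a root sequence from the background composition, diverges
one ancestor per subfamily from it, and mutates members from their ancestor.
Substitutions land on distinct positions and are drawn from the replacement
probabilities implied by BLOSUM62 (`q_ab ∝ p_a p_b 2^(s_ab/2)`, diagonal
removed), so divergence behaves like protein drift under the scoring matrix
used downstream. Indel events are Poisson per sequence with geometric lengths
(mean 2).

Default study conditions, chosen once to match the scale of a real
glycoside-hydrolase-sized domain family: sequence length 250, within-subfamily
divergence 0.15 substitutions/site, between-subfamily divergence 0.5,
indel rate 0.01, fragments truncated to a uniform 30–90% window (so the 95%
coverage filter has unambiguous truth), full-length records assigned coverage
in [0.95, 1]. Under these conditions the five-subfamily preset's components
equal the truth partition on a contiguous window of the grid (about 1e-25
through 1e-80) that contains the 1e-55 default operating point; between-family
relationships are still significant at 1e-5, so the family is one component at
the loose end. The `singletons_divergent` preset saturates between-subfamily
divergence (every site substituted), giving 50 sequences with pairwise global
identity below 30%.

What the fixtures do **not** emulate: site-rate heterogeneity, domain
shuffling, compositional bias, alignment-length variation of real homologs, or
database-scale size. Passing tests therefore demonstrate the correctness of
the workflow's logic and statistics under controlled divergence, not its
biological accuracy on any particular real family.

## Problem sizes and runtime

The packaged analyses are desk-scale by design: fixtures of 50–200 sequences,
20k pairwise alignments (~1 minute), 51-model singleton libraries (~2
minutes). The all-vs-all stage parallelizes by rows (`n_jobs`/`--threads`)
with a deterministic merged result; everything else is single-threaded.

## Known limitations

- E-values are not BLAST-identical (documented above); use imported BLAST
  tables when exact parity with a BLAST-derived analysis matters.
- The greedy 75% redundancy reduction is order-dependent (longest-first,
  deterministic) like the tools it mirrors, not an optimal clustering.
- Gumbel calibration assumes the null score tail is extreme-value-like;
  the method-of-moments fit is coarse in the far tail, which is acceptable
  here because assignments hinge on rank and on margins of many orders of
  magnitude.
- The progressive MSA (biotite's `align_multiple`) is a guide-tree
  profile-merge without iterative refinement; an external aligner (e.g. the
  provided MAFFT hook) can be plugged into `build_msa` when alignment quality
  is limiting.
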