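# Methods

## Scope and model

`microchrom` analyses the conservation and fate of microchromosomes — the
tiny, GC-rich, gene-dense chromosomes characteristic of bird and reptile
karyotypes — from three kinds of evidence:

1. **pairwise whole-genome alignment chains** (UCSC chain format), reduced
   to reciprocal-best syntenic blocks;
2. **karyotype tables** giving per-chromosome lengths and a clade-specific
   micro/macro size threshold;
3. **binned Hi-C contact matrices** (7-column GInteractions text at 50-kb
   bins), summarised as inter-scaffold heat maps and distance-dependent
   contact probabilities P(s).

The package consumes chains; it does not compute alignments. Upstream
aligner settings can be carried as provenance in the pipeline config but
are never executed.

## Chromosome classification

A chromosome is a microchromosome iff its length is strictly below the
clade threshold (35 Mb for birds and snakes; 45 Mb turtles, 50 Mb
rearranged lizards, 75 Mb tegu, 96 Mb alligator). A length exactly at the
threshold classifies as macro; the tie-break is configurable
(`boundary_is_macro`). Explicit class labels from published karyotype data
override the size rule, because assembly sizes near the boundary are
ambiguous. GC content counts G+C over unambiguous A/C/G/T only,
case-insensitively: soft-masked lowercase bases count normally, N and
IUPAC ambiguity codes are excluded from numerator and denominator (the
treatment of masked bases is our choice; common scaffold-statistics tools
count ACGT only). Gene density is genes per Mb.

## Reciprocal-best netting

Chains are filtered by aligned length (100 kb for vertebrate pairs, 5 kb
for comparisons against amphioxus-like compact genomes) and netted
greedily: descending score, ties broken by ascending chain id, a chain
accepted iff its forward-strand span overlaps previously accepted spans by
at most `overlap_tol` bp (default 0) on **both** genomes. This is a
single-level net — only top-level blocks, no subnet hierarchy — because
every downstream statistic consumes top-level syntenic blocks. The greedy
definition is deliberately simple enough to verify against a brute-force
pairwise re-derivation; the test suite and acceptance script do exactly
that on hundreds of random instances. Note that greedy-by-score is not
guaranteed to maximise total accepted score on adversarial inputs; with
scores proportional to aligned length (as axtChain scores effectively are)
the accepted set is monotone under the length filter.

Coordinates are 0-based half-open throughout; negative-strand query
coordinates are kept as given (on the reverse complement) with a
`forward_interval()` helper at the boundary.

## Micro-fraction statistic

For an ordered species pair, the micro-fraction is the proportion of the
query species' microchromosome alignment that lands on target
microchromosomes, weighting each block by its aligned bp. Length weighting
(not chain counting) is used because it is invariant under chain
fragmentation: splitting a block into two abutting blocks changes no
fraction. The count-weighted variant is exposed for comparison and is
demonstrably not fragmentation-invariant. The query×target matrix of
fractions has diagonal 1.0 by convention and records missing pairs as
absent (NaN), never as 0. The matrix is intentionally asymmetric: a
lineage that fused micros into macros keeps a high fraction as query (its
surviving micros still match ancestral micros) but a low fraction as
target.

"Sufficient homology" for partner profiles defaults to 100 kb of aligned
support (`min_support`), matching the vertebrate chain filter.

## Event calling

For each target chromosome, blocks are aggregated per query ancestor
(dropping ancestors under `min_support`), ordered along the target, and
classified by a deterministic cascade:

1. single same-class ancestor with **reciprocal** coverage ≥ `f_intact`
   (default 0.8: ancestor covers ≥ 80 % of the target and the blocks cover
   ≥ 80 % of the ancestor) → conserved. Reciprocity matters: a fission
   product can cover its target completely while using only part of its
   ancestor. The 0.8 default tolerates repeat-driven length expansion.
2. ≥ 2 micro ancestors, no macro → micro–micro fusion.
3. micro + macro ancestors → macro–micro fusion. With a centromere
   position, a micro filling ≥ `f_intact` of one arm (and lying mostly
   within it) is a centric (Robertsonian) fusion. Otherwise a micro whose
   span's outer edge lies within `d_term` of a chromosome end is terminal;
   `d_term` defaults to min(5 Mb, 10 % of the chromosome). Without
   centromere data the terminal label deliberately covers centric fusions
   too, since a fused whole arm also reaches a chromosome end and chain
   data alone cannot separate the two. Two or more macros only →
   macro–macro fusion.
4. all ancestry from one query macro without reciprocal coverage →
   fission (new micro or new macro by the target's class).
5. anything else → unresolved, with a note.

Calls are deterministic given the parameters and block set. The coverage
and distance defaults are our operational choices; published event
assignments of this kind are typically made by inspection of homology
plots without stated cutoffs.

## Four-way ancestral-state map

Each aligned target interval is labelled by the (query class, target
class) pair: `macro` (macro in both), `micro` (micro in both), `new_macro`
(micro in query, macro in target), `new_micro` (macro in query, micro in
target) — the golden-eagle-style partition. Overlaps are resolved for the
higher-scoring, then longer, block; losing blocks keep their non-overlapped
parts, so with non-overlapping input (reciprocal-best output) the map
conserves aligned length exactly. Unaligned regions stay unlabelled.

## Hi-C statistics

Matrices are assumed pre-normalized exports; no balancing is applied. The
inter-scaffold heat map restricts to the N largest scaffolds (N = expected
chromosome number from cytology, ties broken by name) and reports the mean
interaction per bin pair for every scaffold pair, ordered largest to
smallest; the diagonal cell averages over all ordered bin pairs of the
scaffold including the self-pair diagonal.

P(s) uses 30 logarithmic distance bins from the bin size (50 kb) to 1e8 bp
and reports, per chromosome class, summed counts divided by the number of
intra-scaffold bin pairs at those separations — zero-count pairs included
in the denominator (mean-counts estimator, as in standard Hi-C
distance-decay tools). A unit-sum "probability" mode is provided. The
decay exponent α is the negative slope of a log-log linear fit over bins
with positive P; when comparing classes, both fits should use a common
`s_max` within the smaller class's support (micros are short, so their
curves end early). Whether published P(s) analyses used raw or normalized
counts, or which distance-binning scheme, is generally unstated; these
defaults are our decisions and are configurable.

Region-level P(s) (eagle-style) assigns each 50-kb bin to the ancestral
state covering the majority of it (ties to the earlier interval) and
preserves counts within each state; separations are measured on native
scaffold coordinates.

## Synthetic data generator

The simulator defines the study conditions for all end-to-end tests:

* **Ancestor**: 9 macros + 30 micros (the conserved avian state),
  threshold 35 Mb, log-uniform sizes (macros 45–220 Mb, micros 6–30 Mb),
  GC normal around 0.41 for macros with a +0.07 micro offset (sd 0.01),
  gene densities 17 and 40 genes/Mb for macros and micros. All
  configurable, deterministic per seed.
* **Events**: micro–micro fusion, terminal/centric macro–micro fusion,
  macro–macro fusion, fission, expansion. Fused chromosomes inherit the
  length-weighted mean GC of their parts exactly. Random histories draw
  each chromosome into at most one event; fission breakpoints split off a
  terminal micro-sized fragment (the observed route to new micros) while
  the residue stays macro-sized.
* **Chains**: one chain per conserved piece; fragmentation noise places
  Poisson breaks (default 0.2 per Mb) with unaligned gaps totalling at
  most `gap_frac` (default 2 %) of each segment; scores equal aligned bp.
  Expansion inserts target-side gaps so derived coordinates remain exact.
* **Hi-C**: intra-chromosomal expectation `intra_scale·(s/bin)^(−α_class)`
  (so the class curves coincide at one-bin separation and separate
  beyond it), Poisson counts; trans expectation `trans_base·k^(m/2)` where
  m is the number of micro scaffolds in the pair — each micro individually
  engages in elevated trans contact, so micro–micro (factor k), mixed
  (√k) and macro–macro (1) pairs are strictly ordered for k > 1, and k = 1
  recovers a uniform null.

What the generator does **not** emulate: transposable-element sequence
content (expansion is pure length scaling), inversions and translocations
within chromosomes, lineage-specific duplications, assembly errors, and
Hi-C artefacts (unmappable bins, balancing residue, compartment
structure). Passing the recovery tests therefore shows that the statistics
and callers are correct under the stated model, not that real genomes meet
the model's assumptions.

## Problem sizes used in tests

End-to-end recovery runs use the full 39-chromosome karyotype for chains
and event calling (fast), and a reduced karyotype for Hi-C simulation
(3 macros of 36–50 Mb, 8 micros of 5–15 Mb at 50-kb bins, ~4,000 bins),
which keeps Poisson sampling cheap while leaving every statistic
well-estimated; 20 independent seeds per check. Oracle-equivalence checks
use ≤ 15 chains and ≤ 100 bins per instance, 200 instances per operation.

## Numerical and degenerate-input choices

* Empty micro-alignment denominators raise an undefined-value error rather
  than returning 0 — absence of evidence is not a zero fraction.
* A P(s) class whose scaffolds all have fewer than two bins raises an
  undefined-curve error.
* All tie-breaks (equal chain scores → ascending id; equal scaffold
  lengths → name; bin state ties → earlier interval) are fixed for
  determinism and documented at the call sites.
* Chain and GInteractions writers emit a canonical dialect that
  round-trips byte-identically through their readers.

## Known limitations

* Netting is single-level; nested inversions inside a larger block are
  invisible to the event caller.
* Centric fusions are only separable from terminal fusions when centromere
  positions are supplied.
* Breakpoints are resolved to chain ends, not base pairs.
* The CLI analyses one species pair per run; multi-species micro-fraction
  matrices are assembled through the library API
  (`micro_fraction_matrix`).
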