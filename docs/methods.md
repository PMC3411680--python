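# Methods

This note records the models, conventions and numerical choices behind each
stage, what the synthetic-data generator does and does not emulate, and the
known limitations.

## Coordinates and domain model

All internal intervals are 0-based half-open `[start, end)`; the GFF3 and
RepeatMasker `.out` converters own the ±1 arithmetic against those formats'
1-based inclusive conventions. Half-open intervals make containment, gap and
window arithmetic free of off-by-one cases, which the topology stage relies
on. Minus-strand copies keep unflipped genomic coordinates; sequence
extraction reverse-complements on demand, so topology operates in genome
space and dating in sequence space. Non-ACGT ambiguity codes are collapsed
to N on load and N columns are excluded from every substitution count — a
conservative choice that can only discard signal, never fabricate it.

The order → class mapping is fixed: ERV, Copia, Gypsy, LARD, DIRS (the LTR
orders) and Tad, Deceiver, L1, LINE are class I; TIR, Helitron, MITE are
class II; anything unclassified is bookkept as "fragment" and carries no
full-length/incomplete split.

## Annotation refinement

**Fragment joining.** Two consecutive same-family, same-strand fragments are
merged when (a) they are colinear on the family consensus — the second
fragment's consensus start is at or after the first's consensus end, minus a
50 bp tolerance, because alignment ends of genuine fragment pairs commonly
overlap slightly — and (b) the genomic gap between them is more than 80%
covered by other TE annotations. Coverage is measured over the gap only
(not the full joined interval): the gap is the region whose content has to
be explained by nesting. An empty gap counts as fully covered; overlapping
same-family fragments merge unconditionally. Merging runs transitively left
to right; the merged copy takes the union of the consensus spans and the
length-weighted mean identity. Joining is idempotent (tested).

**Simple-repeat filter.** A copy's residual length is its span minus its
overlap with the (merged) simple-repeat track; copies with residual < 20 bp
are eliminated. The subtraction is a filter criterion, not a trim —
surviving copies keep their original coordinates, so downstream topology
sees unmodified intervals. The alternative reading (trimming the overlap
out of the annotation) would fragment intervals and change nest/cluster
relations as a side effect of a noise filter.

**Full-length flag.** A copy is full length iff its consensus span covers
≥ 95% of the family consensus and both termini lie within 10 bp of the
consensus ends. Both thresholds are parameters of `flag_full_length`; the
defaults are our own operational definition (the field has no standard
one), chosen so that modest terminal erosion does not disqualify a copy but
internally-deleted or one-sided matches do.

## LTR insertion dating

Model: the two LTRs of an element are identical at insertion; each lineage
then accumulates substitutions independently at rate r per site per year.
The pairwise divergence of the two LTRs therefore corresponds to 2·age
years of evolution, giving

    T = K / (2 r),   K = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q)

with P and Q the transition and transversion fractions over comparable
(both-ACGT) alignment columns, and r defaulting to 1.3e-8 — the
grass-retrotransposon rate conventionally borrowed for fungal LTR elements.
Gap and N columns are excluded from P and Q entirely (including
gap-adjacent ones).

Alignment is global pairwise with affine gaps (match +1, mismatch −1, gap
open 10, gap extend 0.5; configurable). Pairwise alignment suffices because
dating only ever compares two sequences; a progressive multiple aligner
would add nothing but nondeterminism. Among co-optimal alignments the
aligner's first enumeration is taken, which is deterministic for fixed
inputs. Sequences under 30 bp are refused as undatable degenerate LTRs.

Saturation (1−2P−Q ≤ 0 or 1−2Q ≤ 0) leaves K undefined; saturated pairs are
excluded from age histograms but counted and reported, since silently
dropping them would bias the age distribution young.

Expansion-period bins default to (0, 0.5], (1, 5], (10, 57] million years,
closed-lower/open-upper, matching the three expansion periods reported for
*L. bicolor*. A family is counted once in every bin containing at least one
of its dated copies; copies dating into the inter-period gaps are tallied
as "other". Dating is per copy, aggregated to families afterwards — the
family-level question ("when did this family expand?") is answered by the
distribution of its copies' ages.

A family is flagged potentially active when it has ≥ 2 full-length copies
with identity to consensus strictly above 95%.

## Topology

* **Nests:** strict containment with ≥ 1 bp flank on both sides; each
  insert reports its smallest enclosing host, so chains A ⊃ B ⊃ C yield
  (A,B) and (B,C). Implemented with an interval tree; the test suite checks
  equivalence with an all-pairs brute force.
* **Clusters:** single-linkage chaining of copies whose end-to-start gap is
  ≤ 10 kb; overlapping copies (gap ≤ 0) always chain; a cluster needs ≥ 2
  members. The gap is measured between interval ends, the visual notion of
  adjacency. Equivalent to the transitive closure of the pairwise ≤ 10 kb
  relation (tested against brute force).
* **Density:** non-overlapping consecutive 10 kb windows; a copy counts in
  the window containing its start, so window sums conserve copy number
  exactly. A step parameter below the window size gives true sliding
  windows at the cost of that conservation.
* **Terminal enrichment:** a nest/cluster span is terminal iff it overlaps
  the first or last 1 Mb of its chromosome; chromosomes shorter than 2 Mb
  are wholly terminal (logged).
* Nests and clusters are reported separately plus a deduplicated union for
  the "nested and/or clustered" fraction, since a nested pair inside a
  cluster would otherwise be double-counted.

## Genome summary

Per order: families with ≥ 1 copy, copy count, full/incomplete split, DNA
amount as the sum of copy spans (each copy counts its full span even where
copies overlap through nesting — this keeps rows additive into subtotals),
and percent composition = 100 · Mb / genome Mb. A deduplicated `masked_mb`
column (union of the row's intervals) is emitted alongside for
transparency. Genome size is an explicit parameter, not inferred from the
FASTA, so summaries of annotation subsets remain comparable. Fragment rows
carry no full/incomplete split; total rows therefore satisfy
full + incomplete ≤ copies, with equality on pure order rows. Average
density is copies per Mb, rounded to the nearest integer for reporting.

## Phylogeny

Distances are uncorrected p-distances over both-non-gap columns by default.
The Poisson correction −ln(1−p) is available and logged when used; the
default favours transparency over guessing a legacy program's settings, and
clade structure should be robust to the choice (not asserted as a test).
Neighbor joining follows the canonical Q-matrix agglomeration with ties
broken by the lexicographically smallest index pair (determinism), limb
lengths from the standard two-point formula, negative estimates clamped to
zero and counted, and the final three lineages connected by the three-point
closed form. NJ is consistent on additive matrices; the suite verifies
exact recovery of random additive trees (n ≤ 8) and cross-checks topology
against an independent NJ implementation. Bootstrap resamples alignment
columns with replacement, rebuilds the tree per replicate, and reports the
frequency of each internal bipartition of the full-data tree; fully seeded.

## Synthetic-data generator

The simulator emulates a TE-rich compact genome: by default 3 chromosomes
of 1 Mb carrying ~280 copies from 10 families (Copia > Gypsy among LTR
superfamilies, plus LARD, TIR, LINE, MITE), insertion ages drawn from a
mixture over the three expansion periods (weights 0.30/0.35/0.35 over
0–0.5, 1–5 and 10–57 My), truncation probability 0.4 with the truncated
fraction uniform on (0.2, 0.8) from either end, nesting probability 0.2 and
clustering probability 0.4 with anchor gaps uniform on (200, 10000) bp.
These defaults are fixed study conditions, chosen to mirror the structural
features the pipeline must detect at desk scale; the scale (3 × 1 Mb) keeps
the full suite fast while leaving hundreds of copies per run.

Substitutions follow the exact two-rate (K2P) Markov process — per-site
category probabilities computed from the closed-form transition matrix at
the copy's age, with overall rate r and transition:transversion rate bias
kappa = 2 — i.e. precisely the model the dating estimator inverts, so age
estimates are asymptotically unbiased and the estimator can be validated
without model-mismatch confounds. Each LTR lineage evolves independently;
no indels by default. LTR consensi carry identical terminal repeats, TIR
consensi inverted ones.

Nested insertion splits the host's genomic span; the truth record keeps one
host entry spanning the interruption — exactly the representation fragment
joining is meant to reconstruct. Truth cluster labels are assigned by an
independent brute-force transitive closure, not by the topology module, so
end-to-end recovery checks are not circular. Placement retries avoid
accidental strict containment; with the default cluster probability,
incidental proximity clusters still arise, and truth records them.

What the simulator does **not** emulate: simple-repeat/microsatellite
co-occurrence, indel evolution, GC heterogeneity, segmental duplication,
solo-LTR formation, and annotation error (the truth GFF3 is a perfect
annotation). Passing end-to-end tests therefore demonstrates correctness of
the pipeline's logic under its own model assumptions, not robustness to
real-world annotation noise.

## Determinism and degenerate inputs

Every stochastic component takes an explicit seed; identical configuration
yields byte-identical FASTA/GFF3/TSV outputs (tested). Degenerate cases:
empty annotation files produce empty outputs and header-only tables; a gap
of 0 bp counts as fully covered in joining; copies without consensus spans
are incomplete; pairs with no comparable columns are undatable errors;
matrices under 3 taxa are rejected; chromosomes shorter than twice the
terminal region are wholly terminal.

## Known limitations

* Fragment joining considers fragments pairwise left-to-right; pathological
  interleavings of many families could in principle join differently than a
  global optimisation would.
* Dating assumes a strict clock and no rate variation among sites; ages of
  old elements are compressed by saturation even before the hard
  saturation cutoff.
* The identity values used by the activity flag come from the input
  annotation and are not re-estimated by alignment.
* The published-table bookkeeping reproduces the source table's own
  arithmetic; two of its printed leaf Mb values are mutually inconsistent
  with their printed subtotal at the 0.01 Mb level, so megabase arithmetic
  is validated at the group-row level where the printed figures are
  self-consistent.
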