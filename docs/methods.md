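# Methods

This note records the models behind each module, the parameter choices that
matter, what the synthetic data does and does not emulate, and the numerical
conventions — the things a maintainer would want to know before trusting or
changing a default.

## Gene orders as signed permutations

A mitochondrial gene order is a circular arrangement of a fixed 17-symbol
alphabet (atp6, atp8, atp9, cob, cox1–3, nad1–6, nad4L, rps3, rnl, rns),
each gene appearing exactly once, its sign giving the strand.  All analysis
happens on linearizations canonicalized at `+rns`: the order is rotated so
rns comes first and, if rns is on the reverse strand, reflected (reversed
with all signs flipped) first.  Canonicalization makes permutation identity
well-defined for circular molecules and is idempotent.  Unequal gene
content and duplicated genes are hard errors — rearrangement inference
requires a bijection between the two gene sets, which is also why tRNAs
(frequently lost or multiplied) are excluded from the default alphabet.

### Common intervals and the strong interval tree

A common interval of two orders is a gene set occupying consecutive
positions in both, signs ignored.  Enumeration is exhaustive over the
O(n²) intervals of the first order with an O(n) contiguity check — cubic
overall, which is fine for n ≤ ~40.  Strong intervals are common intervals
that overlap no other common interval; they form a laminar family and hence
a tree whose leaves are the n singletons.  Inner nodes are classified by the
quotient permutation (the order the child blocks take in the second
genome): identity → linear increasing, reversal → linear decreasing,
anything else → prime.  A useful structural fact: quotients of strong
interval tree nodes are always identity, reversal, or *simple* prime (no
non-trivial contiguous sub-block), which the scenario logic relies on.

### Scenario inference

The target order is renamed to the identity, so scenario construction
becomes sorting a signed permutation.  The strong interval tree of the
renamed source is processed recursively; each node is solved to either
ascending-positive or descending-negative orientation (the latter when an
enclosing inversion will flip it):

* children already in desired order: recurse only;
* children in exactly reversed order, two children: four candidate routes —
  transposition (both children solved to the node's orientation),
  inversion (both to the opposite), or an inverse transposition (one child
  each way) — scored by recursive cost; equal costs resolve by the fixed
  precedence transposition > inversion > inverse transposition > TDRL,
  matching the transposition-dominated regime observed in fungal
  mitogenomes;
* children reversed, more than two: whole-block inversion versus a TDRL
  realization, by cost;
* prime node: children solved positive (negative singletons first
  normalized by single-gene inversions, so the TDRL machinery stays
  unsigned and the cost is counted honestly), then the quotient is realized
  by TDRLs.

A whole-region TDRL duplicates the region in tandem and keeps one copy of
each gene: the result is (elements of keep-set 1 in current order) followed
by (keep-set 2 in current order) — exactly a stable binary partition pass.
Sorting an unsigned permutation therefore takes ⌈log₂ r⌉ TDRLs, where r
counts the maximal ascending runs of the position sequence read in value
order (equivalently 1 + #{v : pos(v+1) < pos(v)}); the constructive
algorithm is LSD radix sorting on greedy run labels.  This bound is
verified exhaustively against breadth-first search for n ≤ 5 and on a
sample for n = 6 in the tests.  Note the run statistic is on the *inverse*
reading: counting ascending runs of the permutation itself overstates the
bound (e.g. (3 1 4 2) sorts in one TDRL).

TDRL inverses are not TDRLs, so only the source→target direction is
realized; evaluating the opposite direction would break replay validity,
which is the one guarantee every scenario carries: folding
`apply_operation` over the ops maps the source to the target, asserted on
every construction.  Whole-scenario minimality is *not* guaranteed — the
derivation is a tree-guided heuristic — but single transpositions and
inversions are recovered exactly (length 1, correct kind; verified
exhaustively at n = 8), and single inverse transpositions / TDRLs within
length 2 (ambiguous patterns exist: e.g. an inverse transposition of two
singleton blocks is indistinguishable from an inversion pair of equal
cost).

### Ancestral reconstruction

Bottom-up assignment on a rooted (binary) tree: a node whose children agree
inherits the shared order; otherwise candidates are the children's orders
plus every intermediate along the inter-child scenarios in both directions
(the prefix images), scored by summed scenario length to the children plus
a context term (the majority leaf order of the sibling subtree).  Score
ties break toward the majority order among the node's own subtree leaves,
then deterministically by candidate order; a node whose minimizer is unique
is flagged `consistent`, otherwise `fallback`.  A refinement phase then
sweeps the tree (up to 10 sweeps), re-optimizing each internal node against
its assigned neighbors (children and parent) and accepting strict
improvements, until a sweep changes nothing.  The root deserves caution:
when both root edges carry events the root order is not identifiable from
leaf data, and the majority tie-break is what keeps the estimate sensible.

## ORF scanning and translation

Translation uses the mold mitochondrial code (NCBI table 4): TGA is
tryptophan, TAA/TAG stop, and initiation may use ATG, TTG or GTG (the
latter two observed at cox1/cox3 in fungal mitogenomes).  The scanner
reports maximal ORFs — the longest in-frame allowed start per stop — and
suppresses sub-ORFs by default.  Circular genomes are scanned on the
logically doubled sequence; calls starting beyond the original length, or
longer than the genome, are discarded, and when an origin-crossing ORF and
a shorter internal ORF share a stop the longer one wins.  Raw scanner
counts are *not* comparable to curated genome annotations (which rest on
homology and transcript evidence), so no test asserts a total ORF count.

Coverage statistics count each genome position once per feature class
(union, not sum), so overlapping annotations do not inflate coverage; the
published fractions for the reference genome do not state their overlap
convention, and the union reading is this package's choice.  Percentages
round half-up to one decimal; AT content (N excluded) rounds half-up to an
integer, matching the reporting granularity of genome papers.

## Duplication detection and characterization

`find_repeats` indexes exact words (default 11 bp), groups hits by
diagonal, and extends ungapped with an X-drop rule (match +1, mismatch −2,
drop 12), reporting maximal pairs above length 100 and identity 90% —
defaults chosen to emulate a dotplot inspection, since the original
dotplot tool has no published thresholds; all are config-exposed.  Inverted
repeats are detected against the reverse complement and flagged; pairs with
less than 1 bp between spans are flagged tandem; circular genomes are
scanned across the origin.  Detection boundaries carry a few base pairs of
fuzz when the sequence flanking a repeat matches by chance — inherent to
any local-similarity definition — so structure is measured by
`characterize_duplication`: a global pairwise alignment of the two copies
(match 1, mismatch −1, gap open 5 + 0.5/bp extension; affine gaps are what
make 100–500 bp indel blocks recoverable as single events).  Gap runs of
≥ 10 bp count as insertion/deletion structure; shorter indels fold into the
identity figure and are tallied separately (`small_indel_bases`) so that
span = duplicated_length + own insertions + own small indels holds exactly.
An insertion in one copy and the corresponding deletion in the other are
the same physical event reported from both sides.

## ORF conservation

A reference ORF (plus optional flanks) is aligned semi-globally to the
orthologous region; the ORF is projected through the alignment.  Status
precedence: absent (ORF coverage < 50% or identity below cutoff — the 50%
is this package's choice, since published descriptions of "missing
completely" give no number) > frameshift (net indel length inside the ORF
≢ 0 mod 3 — *net*, so compensated indel pairs do not disqualify) >
premature stop (read through the reference codon frame, deleted codons
skipped; stops inside insertions are only considered for small in-frame
inserts) > start lost (projected start codon outside the allowed set) >
disrupted by insertion (an in-frame insert ≥ 60 bp, a distinct class
because a long in-frame insert breaks a protein without shifting the
frame) > intact.  A panel is `likely_coding` only when every taxon is
intact and at least `min_taxa` (default 4) taxa were examined; any
premature stop, frameshift or absence makes it `unlikely_coding`.

## Diversity, recombination, diagnosability

π is the uncorrected average pairwise per-site difference,
Σ_{i<j} d_ij / (C(n,2)·L_eff), with pairwise gap deletion by default
(a column contributes to a pair only when both carry A/C/G/T; L_eff counts
columns where ≥ 2 sequences carry a nucleotide); complete deletion is a
switch.  No Jukes–Cantor correction — π is reported on the scale
population-genetics software prints by default.  Windows (default 100/25)
are on alignment coordinates.

The four-gamete test runs over biallelic parsimony-informative sites; a
site pair is incompatible iff all four gamete combinations occur,
gap-bearing sequences excluded pairwise.  Recombination *blocks* are called
only when incompatibilities have positional structure: the statistic is the
number of greedy maximal runs of consecutive sites that are pairwise
compatible within the run; a permutation test shuffles site order, and
blocks are reported only when the observed run count is significantly
small (α = 0.05, 999 permutations).  Scattered homoplasy — incompatible
pairs within as well as between loci — yields no blocks, which is the
biologically expected outcome for clonal mitochondria with parallel
mutation.

Outlier strains are quantified as focal substitutions: columns where the
focal strain differs from the single base shared by *all* conspecifics,
columns with any gap among the compared strains excluded ("not considering
indels").  The counts are computed on the concatenated loci; a per-locus
mode falls out of slicing the alignment.  A fixed difference for a species
pair requires full within-species monomorphism at the column; one shared
polymorphism therefore breaks diagnosability — deliberately strict, because
a single misplaced strain is exactly what makes a barcoding locus fail.

## Synthetic data: what it emulates, what it does not

All generators are pure functions of (parameters, seed) with one explicit
`numpy` Generator per call; outputs are byte-reproducible and accompanied
by truth logs sufficient for every recovery test.

* **Gene orders** evolve along a rooted tree with Poisson event counts per
  edge.  Default rates (transposition 0.2, inversion 0.01, inverse
  transposition 0.01, TDRL 0.03 per edge) encode the sparse,
  transposition-dominated regime seen across Pezizomycotina mitogenomes —
  roughly a dozen events over a 22-taxon tree, transpositions dominating,
  TDRL rare, inversions essentially absent outside one divergent clade.
  Recovery experiments additionally cap events at 3 per edge and draw
  operand spans disjointly on an edge ("well-separated"), the regime under
  which ≥ 90% exact recovery of internal orders is demonstrated.  Operands
  are uniform over valid blocks; TDRL keep-sets uniform over non-trivial
  bipartitions.
* **Genomes** are i.i.d. at 72% AT (the composition of the reference
  mitogenome) with planted ORFs (in-frame TAA/TAG scrubbed to sense
  codons — TGA is fine under table 4 — and an upstream in-frame stop
  planted so the planted start is also the maximal start) and an optional
  duplication built as flank + ORF + flank with a specified insert or
  deletion in copy B.  The default layout (124 + 225 + 37 bp unit, 488 bp
  insert after 138 bp) mirrors the interrupted atp9 duplication
  arrangement.  Not emulated: introns, tRNA clusters, compositional skew,
  repeat families beyond two copies.
* **Locus panels** give each species a private set of diagnostic
  substitutions on a shared ancestral backbone (so every pair is separated
  by at least the requested fixed differences), per-strain polymorphism at
  a per-site rate, short deletions, and optionally reciprocal recombinant
  strain pairs between the first two species (reciprocity is required for a
  crossover to produce all four gametes in a small panel).  Not emulated:
  substitution-model structure (ts/tv bias, rate heterogeneity), coalescent
  genealogies, gene flow.

Because the generators plant exactly the structure the statistics measure,
passing tests show the *inference machinery* is correct and calibrated on
data with known truth; they do not show that real data satisfy the
generators' assumptions (independence across sites, uniform operand choice,
absence of alignment error).

## Numerical conventions and degenerate inputs

1-based inclusive coordinates throughout; origin-wrapping features are
stored once with a flag rather than end < start arithmetic.  Round-half-up
for printed-style percentages.  Empty scenarios for identical orders;
empty repeat lists rather than errors when nothing is found; parsers fail
with located errors (line/row numbers) on malformed input.  All
alignment-based modules use Biopython's `PairwiseAligner`; seeds below
2³¹ everywhere.

## Known limitations

* Scenario minimality is heuristic; only the single-operation and TDRL
  bound guarantees are proven properties.
* The root order of a tree is unidentifiable when both root edges carry
  events; the majority tie-break is a convention, not inference.
* Very long scenarios (e.g. between genomes with opposite overall
  orientation) are computed but should be treated as unreliable, as any
  rearrangement-based reconstruction at that distance is.
* The ORF-status classifier trusts the pairwise alignment; in low-identity
  regions (< ~60%) projection errors can shift indel positions by a few
  bases, though the status classes themselves are robust in the tested
  ranges.
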