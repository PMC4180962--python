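# Methods

This note documents the models behind each pipeline stage, the
parameters that matter, what the synthetic-data generators do and do
not emulate, and the numerical choices made where the design was
genuinely open.

## Coordinates and the genome model

Internal coordinates are 0-based half-open; GenBank's 1-based inclusive
convention is converted at the I/O boundary only. A gene wrapping the
origin of a circular replicon is stored as two segments under one gene
id; its position for distance purposes is the midpoint of the full arc.
Gene position is always the midpoint — the only choice symmetric under
strand flips — and inter-gene distance is the minimal arc between
midpoints (plain difference on linear replicons).

For the coding/non-coding partition, coding intervals are merged
strand-insensitively (the focal motif GCGCGC is its own reverse
complement, so strand carries no information) and the non-coding set is
the exact complement; the two tile the replicon. Motif occurrences are
counted overlapping — (GC)ₙ repeats make the overlap convention
material, and the sensitive choice is deliberate — and each interval is
scanned independently so concatenation junctions can never spell
artifactual matches.

## Orthology

Reciprocal best hits require a *unique* best bitscore in both
directions. Bitscore ties are resolved lexicographically by subject id
(logged), with a `drop` policy available for users who prefer to
discard ambiguous genes. The coverage filter keeps a pair only when the
aligned core — the column span between the first and last column where
both rows carry a residue — covers at least 70% of **both** sequences,
boundary inclusive. The wording of the coverage criterion admits an
"either sequence" reading; both-sequences is the stricter default and a
flag (`require_both=False`) provides the alternative. Core groups are
complete cliques (all N·(N−1)/2 pairs present), not transitive
closures, which prevents paralog chaining.

The built-in pairwise aligner is a standard affine-gap global protein
aligner (BLOSUM62, gap open 11, extend 1, free terminal gaps);
externally produced alignments can be supplied instead.

## Alignment filtering and distances

The column filter retains a column iff its gap fraction is ≤ 0 (by
default: any gap removes the column) and the majority residue reaches
50% of rows. Alignments retaining < 75% of their columns are flagged
for exclusion from tree building — the gate that keeps truncated or
pseudogenized sequences from masquerading as topology changes. The
filter is a deliberate two-parameter simplification of block-based
alignment cleaning; only the 75% retention gate is behaviourally
relevant downstream.

Protein distances are Poisson-corrected p-distances, d = −ln(1−p),
over mutually ungapped retained columns. Because every downstream
statistic is normalized per tree, the simple correction is adequate; a
richer scorer can be plugged in.

## Neighbour-Joining

Canonical Saitou–Nei agglomeration with the Studier–Keppler Q
criterion. Ties in Q are broken toward the pair whose representative
(smallest-contained-leaf) names sort first, making output fully
deterministic. Negative branch-length estimates are clamped to zero
with the deficit logged. On additive matrices the implementation
recovers the generating topology and all patristic distances to 1e-9
(verified against an independent NJ implementation in tests).

## Movement scores and transfer calls

Per-tree distance matrices are patristic distances divided by the
tree's total branch length, which makes them invariant to global rate
differences between genes; the consensus matrix is the element-wise
mean over all trees congruent with the consensus topology (plurality
topology among gene trees; a reference tree can be supplied to break
ties). "Congruent" is operationalized as unrooted Robinson–Foulds
distance 0.

The movement score is the sum of absolute deviations between a gene
tree's normalized distances for taxon j and the consensus entries. The
absolute-deviation form directly expresses "amount of movement"; a
squared-deviation variant sits behind `form="sq"` and passes the same
recovery tests. Scores are only computed for incongruent trees
(RF > 0): for congruent trees the movement is noise by construction.

Calling rules: recipient = argmax S (ties reported and flagged
ambiguous); donor = the taxon with the most negative change in
normalized distance to the recipient among taxa that got closer;
UNKNOWN when every distance to the recipient increased. Deltas use the
same normalized matrices as the score itself, for internal consistency.

## Co-localization statistic

Distance categories are fixed at (0, 1 kb], (1 kb, 10 kb],
(10 kb, 100 kb], (100 kb, 1 Mb] — operon scale, gene scale, and two
successive orders of magnitude. The expected frequency of a category is
the uniform-placement null on a circle: two independent uniform points
have min-arc distance in (a, b] with probability 2(b−a)/L (b ≤ L/2;
bounds beyond L/2 are truncated with a warning). That closed form *is*
the genome-length normalization — no further rescaling is applied, and
the reported absolute log-ratios depend on this reading. A seeded
Monte-Carlo expectation mode exists and agrees with the analytic form
within sampling error (asserted in tests). Log base is 10; a category
with zero observed pairs reports −inf as an explicit sentinel; pairs
beyond 1 Mb are counted as out-of-range mass.

## Metabolic network and cross-clustering

A compound is treated as a currency metabolite and discarded iff
strictly more than `max_links` = 10 *distinct genes* are annotated to
it ("links" could alternatively count edges; the gene-count reading is
the implemented default and both the definition and threshold are
configurable). Surviving compounds connect all pairs of their genes.
The genomic-edge predicate is: same operon, or midpoint distance
≤ 10,000 bp (inclusive — "not greater than" the average operon
length). Nodes with fewer than two metabolic neighbors have no neighbor
pairs, so their coefficient is undefined; they are excluded from the
genome-wide mean and reported separately rather than counted as zeros.

Operons come from an input table when available; the built-in fallback
predicts them as maximal same-strand runs with intergenic gaps
≤ 100 bp, merging across the origin of circular replicons when
compatible.

## Breakpoints and motif enrichment

Two signed ortholog orders are first restricted to their shared
identifiers; an adjacency (x, y) is conserved iff (x, y) or (−y, −x)
is adjacent in the other order, with circular orders closing the cycle.
Non-conserved adjacencies are breakpoints; their coordinate is the
midpoint of the broken intergenic gap. This adjacency method stands in
for alignment-based synteny blocks; a block-table importer covers
fidelity runs with external aligners.

Flank enrichment counts the motif in the *union* of ±40 bp windows
(overlapping windows merged, never double-counted; windows clipped at
linear ends, wrapped on circles) and divides the per-10-kbp flank
density by the whole-replicon density. Note the denominator includes
the flanks themselves, so the estimator is slightly conservative; with
flanks under 1% of the genome (the realistic regime: 200 breakpoints ×
80 bp on a ~2 Mb chromosome) the bias is ~2%.

## Substitution skew

Counts come only from columns where both rows carry one of the 20
standard residues; gaps and X are skipped. The normalizer
M[A1] + M[A2] (the identity-match counts of the two residues) is the
reading of "numbers of matches of amino acids A1 and A2 in both
genomes" that uses both named quantities symmetrically; a total-column
normalizer is available by flag and the choice is recorded in the
output table. Antisymmetry and sign-flip-under-reference-swap are exact
algebraic properties and are asserted as such.

## OU stratigraphy

Oligonucleotide-usage patterns are overlapping k-mer frequencies
(k = 4 by default) summed over both strands and normalized to total 1;
windows containing N contribute nothing. The island–host distance is
the mean absolute frequency difference scaled by 4^k — robust to the
sparse vectors short islands produce. Larger distance ⇒ more recent
acquisition (amelioration has had less time to erase the donor's
signature); sequences much shorter than ~40·4^k/10 bp trigger a
warning because their pattern estimate is noisy.

## Synthetic data: what it emulates and what it does not

* **Genomes**: circular chromosome (default 2 Mb, 600 genes) packed
  with co-directional operons whose sizes follow a truncated geometric
  distribution (mean 3, matching typical bacterial operon statistics);
  intra-operon gaps 20–100 bp, inter-operon gaps ≥ 150 bp plus an even
  share of the remaining length so operons cover the whole circle.
  Pathways annotate contiguous gene runs within one operon with a
  shared compound; a leakage rate swaps participants for random genes.
  Not emulated: plasmids, gene overlap, regulatory features, realistic
  gene-length distributions.
* **Gene trees**: clones of a five-taxon species tree (two
  *T. thermophilus* strains, *T. scotoductus*, two *Meiothermus*
  species — the shape of the studied five-genome comparison) with
  multiplicative lognormal branch-length noise (rate variation keeps
  lengths positive). A transfer shrinks the donor–recipient patristic
  path to 20% of its length and regrafts the recipient beside the
  donor — the signature the caller is designed to read. Sister-leaf
  transfers are topologically invisible to an RF-gated caller and are
  excluded from recovery measurements. Not emulated: explicit sequence
  evolution, within-gene recombination, incomplete lineage sorting.
* **Motif planting**: pre-existing motif occurrences are scrubbed, then
  copies are placed by rejection sampling at rate r in the background
  and fold·r in breakpoint flanks; because the motif is periodic, a
  post-pass destroys unintended occurrences created by adjacency so
  realized counts are exactly the planted ones.
* **Proteome pairs**: gap-free ortholog alignments; each site is
  identical with probability 0.9, otherwise the partner residue is
  drawn uniformly over the other 19 with the planted directional excess
  added to specific channels before renormalization. Not emulated:
  site-rate heterogeneity, empirical exchangeability matrices,
  indels.

Consequently, passing tests demonstrate that each statistic recovers
exactly the signal it is defined to measure under controlled
conditions; they do not validate biological conclusions on real
genomes, where alignment error, paralogy and annotation noise enter
upstream of these statistics.

## Problem sizes and determinism

The reproduction script and the test suite run everything at desk
scale: 100 random additive matrices (5–10 taxa) for NJ, 100 gene-tree
sets of 11 trees for transfer recovery, 100 random networks (≤ 25
genes) for the cross-clustering oracle, 100 rearranged orders, 2-Mb
sequences with 200 breakpoints for fold enrichment, 150 × 50-alignment
proteome sets for skew, and 50 amelioration series. All generators are
bit-reproducible given their seed, and every reported number is
computed at run time from freshly generated data.

## Known limitations

* The movement-score caller assumes a single transfer per gene tree;
  multiple simultaneous transfers blur the argmax.
* The analytic co-localization null assumes genes positioned uniformly
  and independently; real gene density varies along the chromosome.
* The built-in operon predictor is purely structural (strand + gap);
  it knows nothing about transcription signals.
* Poisson-corrected p-distances saturate near p → 1 and raise rather
  than extrapolate.
* The fold-enrichment estimator divides by whole-genome density
  including the flanks (see above); callers comparing very dense
  breakpoint sets on short replicons should expect the conservative
  bias.
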