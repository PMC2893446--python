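# Methods

`omiclink` is a headless re-implementation of the analytic core of a
linked-view exploratory-analysis engine for integrated translational
cancer studies: gene expression, copy-number states from array CGH / SNP
arrays, and clinical data including censored survival. The GUI event loop
of such tools is replaced by a programmatic selection API, and every
graphic by a typed scene description exported to deterministic SVG, so
"interactivity" becomes a testable function: a selection propagated
through the linking engine must light up exactly the corresponding
primitives in every view.

## Data model

All datasets share one identifier universe managed by a registry (the
"data manager"): genes, samples, markers (CGH clones / SNPs),
chromosomes, and derived results. Every identifier resolves to exactly
one class; this is checked on every registration, which is what makes
cross-dataset linking sound. Chromosome names are normalized to
`1`–`22`, `X`, `Y`; coordinates are 1-based closed intervals, with a SNP
as the degenerate `start == end` case. Missing values are NaN in both
matrix types; each operation states its own policy (pairwise-complete
distances, row-mean imputation in k-means, hard error inside a
mean-squared-residue computation).

A sample may appear in the clinical table but not in the expression
matrix; it then simply contributes no matrix column while remaining
selectable through the shared sample universe. We deliberately do not
fabricate empty matrix columns for such samples: keeping matrices exactly
as ingested avoids silent shape changes, at the cost that such samples
are invisible in matrix-backed views.

## Unsupervised toolbox

**Distances.** Euclidean, Manhattan, and the correlation distances
`1 − r` (Pearson, Spearman on average-rank fractional ranks), range
[0, 2]. Missing entries are handled pairwise-complete; Euclidean and
Manhattan sums are rescaled by `p / p_observed` to stay on the
full-dimension scale. A zero-variance item has no defined correlation:
its distances are reported missing and logged, never silently zeroed,
and clustering refuses matrices containing such holes rather than
guessing.

**Hierarchical clustering** is Lance–Williams agglomeration (scipy)
with single, complete, average and Ward linkage; Ward is restricted to
Euclidean input where its variance interpretation holds. Flat partitions
come from cutting the `k − 1` highest merges; labels are canonicalized
to `1..k'` by order of first appearance so results are deterministic
across platforms. Tests verify merge heights *and* cluster compositions
against a naive O(n³) re-agglomeration oracle for all four linkages, and
single linkage against hand-rolled Prim MST edge weights.

**k-means** wraps scikit-learn's Lloyd iteration with k-means++ seeding
— a randomized farthest-point-style initializer — taking the best of 10
seeded restarts by within-cluster sum of squares; deterministic given the
seed. Rows with missing entries are imputed by their own row mean for
this operation only, with a logged count.

**Seriation.** Three orderings: scores on the first principal component
(SVD of the column-centred matrix), the first classical-MDS coordinate
(Torgerson double-centring + leading eigenvector — written out here
because the common MDS implementations are SMACOF, not classical
scaling), and optimal leaf ordering of a dendrogram. The PCA/MDS axis
sign is arbitrary; it is fixed deterministically (largest-|loading|
coordinate positive), and an ordering and its reverse are treated as the
same seriation. Degenerate input (all items identical) yields the
identity permutation with a log message rather than an error.

**Optimal leaf ordering** is the exact dynamic program over the
2^(n−1) tree-consistent orders: for every subtree and every feasible
(leftmost, rightmost) leaf pair the minimal internal adjacent-distance
sum is tabulated bottom-up, with the combine step written as two
min-plus products. We implemented this ourselves after finding that the
scipy implementation in the pinned environment returns non-optimal
orders on a substantial fraction of small random instances when checked
against exhaustive enumeration; the test suite keeps that enumeration as
the oracle. Cost is roughly cubic on balanced trees — comfortable at the
tens-to-hundreds-of-items scale these views operate at.

**Cheng–Church δ-biclustering.** Coherence of a block (I, J) is the mean
squared residue H(I, J) — the mean squared deviation from an additive
row-effect + column-effect model; 0 for any constant or perfectly
additive block. One bicluster is extracted by (1) multiple-node deletion:
while H > δ, drop every row/column whose mean residue exceeds α·H;
(2) single-node deletion of the worst row or column until H ≤ δ;
(3) node addition of any outside column/row whose residue against the
block does not exceed H, guarded so an addition step is committed only
if the recomputed H stays ≤ δ (this makes the δ-bound a hard invariant
rather than a lemma-backed expectation). Found cells are then masked
with uniform noise over the data range from a seeded generator and the
search repeats. Defaults: δ = 0.1, α = 1.2 (mild multiple deletion,
appropriate at the ≤ 1000-row scale), 10 biclusters. The original
algorithm's inverted-row addition is omitted: an inverted member cannot
be represented in the result type without an orientation flag, and none
of the downstream views could display it.

Scores are computed on the working matrix at discovery time; a bicluster
found after earlier maskings may overlap masked cells, which is inherent
to the masking strategy and the reason reported scores refer to the
matrix the algorithm actually saw.

**Bimax.** Inclusion-maximal all-ones submatrices of a binary matrix are
exactly the formal concepts (maximal bipartite bicliques) of the
incidence relation, so they are enumerated exactly: the family of row
column-sets (as bitmasks) is closed under pairwise intersection, each
closed set's extent is computed, and size minima are applied afterwards.
Output is sorted by descending area, then lexicographic row set —
deterministic. A safety valve truncates pathological dense lattices at
200 000 intents with a warning; the test suite compares against
brute-force enumeration over all row subsets up to 8×8.

## Cluster agreement

Two labelings of the same items are cross-tabulated; items lacking a
label on either side are dropped with a logged count. The display sort
maximizes the diagonal sum exactly by optimal assignment on the count
matrix (padded square with zeros, padding dropped from the reported
permutations); a greedy row-wise sort was rejected because the
assignment optimum is exact, deterministic, and testable against brute
force over all permutation pairs. The adjusted Rand index (scikit-learn)
is the numeric companion, tested against explicit pair counting.

## Linking engine

A marker links to every gene whose closed interval it overlaps on the
same chromosome — one shared base suffices, strand is ignored, and the
relation is many-to-many (a clone spanning two genes highlights both).
Overlap queries run through per-chromosome interval trees (half-open
internally; closed semantics restored by `end + 1`). Selection
propagation closes a selection under: result membership (a bicluster
selects its genes and samples; a cluster `name#label` its members) and
the marker↔gene relation, iterated to a fixed point. The closure is
monotone, idempotent and symmetric; all three are property-tested on
random selections over the simulated study. Categorical class colors are
assigned in order of first appearance from a 10-color palette (cycling
with a warning beyond 10 classes), so every view shares one stable
legend.

## Views

Every renderer maps data plus a selection to a scene: a flat list of
rect/line/tick/text/polyline primitives, each carrying the identifier of
the object it depicts and a highlight flag. SVG serialization is
deterministic (fixed attribute order, fixed number formatting), so
re-exporting an identical scene is byte-identical and end-to-end
reproducibility can be asserted on file bytes. Choices worth noting:

* expression colorscale: symmetric diverging blue–white–red, clipped at
  the 1st/99th percentile of the data, exact mid color at the midpoint;
  copy-number states use a fixed 3-color categorical scale.
* missing cells are still emitted, in a designated missing color, so a
  heatmap always has rows × columns cells.
* histogram bins are half-open `[anchor + k·w, anchor + (k+1)·w)` —
  a value on an edge falls in the right bin; anchor defaults to 0.
* the eventchart draws one horizontal line per subject from 0 to the
  observed time with a terminal tick only for observed events (no tick =
  censored); lines group contiguously by a categorical variable, groups
  separated by a blank row. Kaplan–Meier curves are deliberately out of
  scope: aggregate curves cannot be linked bidirectionally at the
  individual level.
* aberration frequencies are per-marker gain/loss fractions among
  samples with a non-missing state (so gain + loss + normal = 1);
  markers with no observed state are omitted with a log.
* highlighting is drawn as a stroke on flagged primitives; bar-shaped
  views draw the selected fraction as a proportional sub-bar.

## Synthetic study generator

The generator emulates a two-subgroup leukemia cohort in which
expression subgroups reflect underlying copy-number aberrations.
Defaults (changeable through `StudyDesign`):

| parameter | default | rationale |
|---|---|---|
| samples | 60 (2 × 30) | small translational cohort |
| genes / markers | 500 / 300 | desk scale, preserves structure |
| background | N(0, 1) per cell | preprocessed log-ratio scale |
| group effect | +2 sd on a 50-gene block per group | clearly separable subgroups |
| planted bicluster | 20 genes × 15 samples, offsets U(−0.5, 0.5), noise sd 0.1 | see below |
| copy-number segments | chr1 gain, all of group 1; chr2 loss, half of group 2 | one full-penetrance and one partial aberration |
| survival | exponential per group (rates 1/60, 1/20 per month) | simplest model with visible group separation |
| censoring | Bernoulli(0.2) per subject; censored time uniform on [0, event time] | makes the censored fraction binomially testable |

Carriers of a segment are the first `round(fraction · group size)`
samples of each group, so planted aberration frequencies are exact
rational numbers that the frequency profile must reproduce exactly.

The planted additive bicluster draws row/column offsets uniformly from
±0.5 — deliberately *below* the background standard deviation. This is a
structural requirement, not a tuning knob: mean-squared-residue
biclustering searches for coherent blocks at the scale of the data, and
a block whose offsets dwarf the background is a magnitude outlier whose
rows are stripped first by greedy deletion. The standalone benchmark
(`planted_shift_matrix`, 30×20 with a 15×10 block) uses the same
convention.

What the generator does **not** emulate: probe-level microarray noise,
normalization artifacts, segmentation errors in the copy-number calls,
correlated gene-gene background, or real genome geometry (two synthetic
chromosomes of 200 Mb and 150 Mb suffice for positional logic). Passing
recovery tests therefore show the algorithms are implemented correctly
and sensitive at realistic effect sizes — not that they are robust to
every artifact of real array data.

## Problem sizes and determinism

All tests and the acceptance script run at desk scale — oracles
enumerate up to 2^(n−1) orders at n ≤ 8, 24×24 permutation pairs, all
row subsets of 8×8 binary matrices; recovery experiments use the
60-sample study over 20 seeds. Every stochastic component (generator,
k-means restarts, Cheng–Church masking) takes an explicit seed, and the
whole simulate → report pipeline is byte-reproducible from that seed.

## Known limitations

* Cheng–Church explores one greedy path per bicluster; it can split or
  trim a planted block when the deletion path commits early (observed at
  small block sizes), and later biclusters may straddle masked cells.
* Views aim at structural fidelity (counts, positions, colors,
  provenance), not typographic polish; text labels are minimal.
* The registry is in-memory only; persistence is the flat-file dialect.
* Selection propagation treats a whole dendrogram as its leaf set; no
  per-subtree selectable ids (individual clusters of a *partition* are
  selectable).
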