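# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic cohorts do and do not emulate, and
the places where the design was genuinely open.

## Harmonization

Input matrices arrive in the tab-delimited series-matrix dialect with
``!``-prefixed metadata and a single table block. Samples are labelled
`affected`, `control`, or `carrier`; carriers stay in the data object but
never enter the differential-expression design, since heterozygous carriers
of a recessive variant are neither cases nor clean controls.

Every dataset is brought onto a common scale before fitting:

1. matrices flagged as pre-logged are reverse-transformed (`x -> 2**x`);
2. if the matrix minimum `m` is at or below zero, all values are shifted by
   `-m + 0.01` (a former zero becomes exactly 0.01). The shift is also
   applied when the minimum is exactly zero — logged, since a zero minimum
   is the boundary of the rule;
3. quantile normalization forces every column onto the mean-of-sorted-columns
   reference; ties within a column receive the average of the reference
   values their sorted positions span (the established microarray
   convention — verified during development to match the Bioconductor
   reference routine to ~1e-15 on random matrices);
4. log2 transformation.

Missing cells are imputed with the row median before normalization and
logged; rows that are entirely missing are dropped. Scale detection (when no
flag is supplied) calls a matrix log2 iff its maximum is ≤ 30, boundary
inclusive — a conventional heuristic, advisory only and overridable per
dataset.

After harmonization all columns carry identical sorted value multisets, so
between-sample distributional artifacts cannot masquerade as differential
expression; within-column rank order of untied values is preserved.

## Differential expression

Per gene, the affected-vs-control contrast is an ordinary least-squares fit:
`log2FC = mean(affected) − mean(control)` with pooled residual variance on
`df = n_a + n_c − 2` degrees of freedom (each group must have ≥ 2 samples).
Variances are moderated by empirical Bayes under a scaled inverse-chi-square
prior: with `e_g = log s_g² − ψ(df/2) + log(df/2)`, the marginal moments give
`d0` by inverting `ψ'(d0/2) = var(e) − ψ'(df/2)` (Newton iteration on the
trigamma function, tolerance 1e-8) and `s0²` from the mean. The posterior
variance `(d0·s0² + df·s²)/(d0 + df)` yields a moderated t on `d0 + df`
degrees of freedom; `d0 = 0` reproduces the classical pooled t exactly and
`d0 = ∞` judges every gene against the common prior. Two-sided p-values are
reported raw; Benjamini–Hochberg values are computed alongside but are
deliberately not used for filtering — with the small group sizes typical of
rare-disease datasets an FDR cutoff empties the gene lists, so the pipeline
filters on raw p and treats cross-dataset recurrence as the real multiplicity
control.

The filtering cascade is ordered and fixed: (1) drop `p ≥ 0.05`; (2) remove
genes whose *surviving* probes disagree in fold-change sign; (3) collapse
same-sign duplicates to the lowest-p probe (ties: larger |log2FC|, then probe
id). The coding filter removes annotated non-coding biotypes and the symbol
prefixes LOC, FLJ, RP. Read literally, the RP rule also removes
ribosomal-protein symbols (RPL/RPS); because the plausible intent is
RP11-style clone identifiers, `rp_prefix_mode="clone_only"` restricts it to
`RP<digits>-` symbols. The literal mode is the default so the documented rule
is the executed rule. Fold-change selection keeps `|log2FC|` strictly above
0.585 (≈1.5-fold) and caps at the top 500 by |log2FC| (ties: ascending p,
then gene id).

## Enrichment

Over-representation uses the one-sided hypergeometric tail on the measured
universe (genes on the platform after the coding filter — the background the
DEGs were actually drawn from). The combined score `−ln(p) × z`, with `z` the
standardized deviation of the observed overlap from its hypergeometric mean,
multiplies significance by effect size; it is a reporting aid, not a
selection criterion. Unweighted GSEA accumulates `+sqrt((N−k)/k)` at set
members and `−sqrt(k/(N−k))` elsewhere (the running sum returns to zero by
construction); the statistic is the signed extreme deviation, `expected` is
`k·pos/N` at the extremum. The null permutes the member positions: exactly,
enumerating all C(N, k) placements when that count is ≤ 200,000, otherwise by
seeded sampling with the +1 correction so p is never zero.

Cross-dataset term selection keeps a term selected (p < 0.05) in at least
`ceil(min_fraction × n)` of a tissue's `n` datasets; the default fraction is
1/3 with the ceiling applied, so 3 datasets require 1 and 4 require 2.
Category rollups report percentage occurrence against a user-supplied
term-to-category map; the grouping is intrinsically curatorial and is not
shipped.

## Pathway expression scores

For one pathway in one dataset, with member DEGs at p < 0.05:

* `rateFC` = (# member DEGs with log2FC > 0) / `n_total`, where `n_total`
  counts pathway members **present in the measured universe**, not the full
  annotation — otherwise platforms with poor coverage would be biased low.
* `normMeanFC` = weighted mean of the normalized histogram of member log2FC
  values: clipped to ±4 log2 units, 20 equal-width bins, frequencies
  normalized to sum 1, bin centers averaged. 20 bins keep the histogram
  smoothing visible (the score is defined through a histogram, not a plain
  mean) while converging to the clipped mean as bins grow; ±4 log2 units
  (16-fold) covers essentially all real microarray fold changes.
* `combinedFC = rateFC + clip((normMeanFC + 4) / 8, 0, 1)`.

The combining function is this package's own construction: the two
ingredients and the required semantics (range [0, 2]; above 1 = majority
over-expression; below 1 = overall under-expression) are fixed, but no
published formula joins them. The affine-clipped sum is the simplest monotone
form meeting the contract — `normMeanFC = 0` contributes exactly 0.5, so a
pathway needs both a majority of up-regulated members and a positive mean
shift to clear 1.0. Scores from any tool using a different combination are
comparable in sign and ordering, not in magnitude. A pathway with no member
DEGs is reported unscored (`rateFC = 0`, combined undefined) rather than
given a fake neutral value.

Gene-level consistency: per gene, the majority sign across the datasets where
it is a DEG; its score is the number of datasets carrying that sign, and it
is *consistent* when the score reaches `max(2, ceil(min_fraction × n))` — the
one-third rule with a floor of two, since a gene seen once cannot be
cross-dataset consistent. An exact up/down tie breaks toward the sign with
the larger summed |log2FC|, then up; ties are rare and the choice only
affects which direction is reported, not whether the gene is flagged.

## Guided walks and the odds ratio

Walkers operate on the largest connected component of the pathway-to-pathway
network (isolated pathways are logged). Guidance mass per pathway is the
count of guide genes annotated to it, pseudocount 0: pathways without guide
genes are never chosen as destinations but are freely visited en route. Each
walker starts at a guide-sampled node (counted once), then repeatedly samples
a destination ∝ mass and traverses one shortest path, counting every node
entered; one edge traversal consumes one step of the 10,000-step budget, and
6 walkers run per analysis with a teleport to a guide-sampled node every 50
destination selections (an alternative steps-based restart unit is
configurable). Ties among equal-length shortest paths are resolved by uniform
random choice among distance-decreasing neighbours, which samples paths
without enumerating them. A destination equal to the current node counts one
visit and one step — this keeps the budget finite in the degenerate case
where all guide mass sits on the walker's current pathway. The topology-only
null is mechanically identical with uniform destinations.

The odds ratio per pathway is
`OR_i = [P_iG/(1−P_iG)] / [P_iT/(1−P_iT)]` with `P_i = F_i/F_t`; pathways
unvisited by the topology run are reported unscorable rather than given an
infinite OR. Louvain community detection (networkx implementation, resolution
1.0, seeded) runs on the walked component with edge weights = guided
traversal counts + 1.

Two caveats are worth stating plainly. First, visit counts along shortest
paths are autocorrelated — a plain multinomial chi-square comparing two runs
is overdispersed and rejects even for two independent topology runs; the test
suite therefore calibrates equivalence checks against the observed dispersion
of topology-run pairs. Second, membership-count guidance is a declared
simplification of gene-network-driven walkers: published walk tools construct
a disease gene network and derive destination scores from it, which this
package does not attempt; results are interpretable as "pathways implicated
by where the guide genes sit", no more.

## PPI modules

Interaction tables (protein1, protein2, combined_score) are thresholded at
0.700 — the conventional high-confidence score cut — keeping edges with score
≥ threshold, collapsing duplicates to the maximum score, and auto-rescaling
the 1–1000 integer score dialect. ECC(u, v) = (triangles through the edge +
1) / min(deg u − 1, deg v − 1); a pendant edge is assigned 0 since the ratio
is undefined there. Module detection sorts edges by descending ECC (ties:
higher score, then lexicographic endpoints — a total order, so the partition
is independent of input edge order) and merges endpoint modules by union–find
while ECC ≥ threshold; components below the minimum size (default 3) are
reported unassigned. This is the plain agglomerative form of
edge-clustering-coefficient module detection; λ-module in/out-degree
refinements of the published algorithm family are intentionally out of scope.

## Synthetic cohorts

The generator emulates a multi-dataset microarray compendium: per-gene
baselines uniform on log2 ∈ [4, 12], i.i.d. Gaussian noise on the log2 scale
(default sd 0.5 — typical residual variability of normalized arrays),
additive mean shifts on affected samples for designated gene sets (default
effects of ±1 log2 unit, a clearly biological but not trivial 2-fold change),
and group sizes of order 10v10 for powered scenarios or 5v5 for null
calibration. A perturbation is active in `ceil(consistent_fraction × n)`
datasets, directly exercising the one-third consistency rule. Dialect options
emit pre-logged, linear, or negative-shifted linear matrices to exercise
every harmonization branch, and an optional two-probes-per-gene mode with a
configurable fraction of sign-flipped second probes exercises the multi-sign
filter.

Gene-set collections draw members from the whole universe when the overlap
fraction is positive, so non-neighbour sets share genes by chance as real
curated collections do (pleiotropic genes recur across many sets); designated
neighbour pairs additionally meet a Jaccard floor. The resulting shared-gene
network at the acceptance scale (100 sets of 15–30 genes over 2,000 genes)
has mean degree ≈ 25, comparable to curated pathway-to-pathway functional
networks; a spanning backbone is added (and flagged) only if the graph is
disconnected. Scored PPI tables plant modules by sampling intra-module pairs
densely above the confidence threshold and inter-module pairs sparsely below
it.

Not emulated: probe-level array artifacts (background, saturation,
batch effects), RNA-seq count noise, correlated gene-gene structure within
pathways, and platform-dependent coverage. Passing tests therefore certify
the statistical machinery — calibration, recovery, determinism, exact oracle
agreement — not robustness to array chemistry.

## Problem sizes and numerical choices

Simulation-based checks run at deliberately modest sizes chosen to keep the
whole suite fast while leaving each check well-powered: 10,000 genes × 3
seeds for null type-I error, 20 seeded runs for guided recovery at the full
6 × 10,000 walk budget, 10 seeds for pathway-score semantics, and a
3-dataset / 600-gene / 20-pathway world for end-to-end determinism. All
generators and walks are bit-reproducible under their seeds; pipeline
artifacts are written with fixed float formatting (`%.10g` for tables,
`%.17g` for expression matrices so round-trips are lossless) and the
manifest records seeds and thresholds, making reruns byte-identical.
Trigamma inversion uses Newton iteration from `y = 0.5 + 1/x` with relative
tolerance 1e-8; moment estimation excludes zero residual variances and
returns the `d0 = ∞` limit when the log-variance spread falls below its
theoretical sampling floor.
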