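# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the limitations of the `loopdiff` pipeline.

## Contact matrices and balancing

Read pairs arrive as 4DN-style `.pairs` text with 1-based positions; they
are converted once at ingest to the 0-based half-open convention used for
every internal coordinate. Pairs are kept when `min(MAPQ1, MAPQ2) >= 30`
(configurable) and PCR duplicates — records identical in both positions and
strands — are collapsed. Only intra-chromosomal (cis) records are retained:
every downstream analysis operates on bounded-separation cis interactions.

Binned matrices store sparse upper-triangle pixels per chromosome. Iterative
correction (ICE) equalizes bin marginals on the cis counts: starting from
unit weights, each iteration divides every unmasked bin's weight by its
balanced marginal relative to the mean, stopping when the coefficient of
variation of unmasked marginals drops below `tol = 1e-5` (default;
`max_iter = 200`, non-convergence is flagged, not raised). Weights are
rescaled at the end so the mean unmasked marginal is exactly 1. Bins with
zero coverage plus the lowest 2% of covered bins are masked; at least one
bin per chromosome is always kept. These masking and tolerance defaults are
declared choices — matrix-balancing conventions differ between
implementations and none is canonical. Balancing is scale-invariant and
never creates or destroys pixels.

The distance-decay profile is the mean balanced count at each bin
separation, per chromosome, with the pooled profile the coverage-weighted
mean (total balanced mass over total unmasked positions at that
separation). No monotone smoothing is applied.

## Negative-binomial differential testing

Counts are modeled NB with `var = μ + φμ²`. Library-size normalization
scales each sample's counts to the geometric-mean library size
(total-count scaling; trimmed-mean scaling is not implemented — the
conditional-likelihood machinery is normalization-agnostic given scaled
counts).

**Dispersion.** The common dispersion maximizes the conditional
log-likelihood of the scaled counts given each group's total, pooled over
all features — the qCML approach of the edgeR family, evaluated with the
continuous-count gamma-function form so that non-integer scaled counts are
handled directly. Per-feature (tagwise) dispersions maximize a weighted
likelihood `l_f(φ) + prior_df · l̄(φ)` where `l̄` is the average per-feature
conditional log-likelihood, with `prior_df = 20` by default; this shrinks
noisy per-feature estimates toward the common value. On simulated tables
the common estimate agrees with edgeR's `estimateCommonDisp` to three
significant figures (cross-checked in the test suite via Rscript).

**Exact test.** For two groups with `n₁, n₂` replicates, the scaled group
sums are NB with dispersions `φ/n₁, φ/n₂`. Conditional on the pooled sum,
the two-sided p-value sums the probabilities of all splits whose
probability does not exceed the observed split's (the standard exact-test
two-sided rule). At `φ = 0` this reduces exactly to a binomial split test,
which the tests verify against direct enumeration. The quasi-likelihood
F-test variant is deliberately not re-implemented; the exact test is the
package's single testing path. log2 fold changes use a pseudocount of 0.5
per group mean. Benjamini-Hochberg correction is applied across tested
features; features with total raw count below `min_count` are excluded from
testing and from the BH family.

**Differential interactions.** The tested universe is every cis bin pair
with `(bin_j − bin_i) × resolution < 1 Mb` at 25-kb resolution. The
diagonal is excluded by default (self-ligation artifacts dominate it);
pairs with total count < 10 across samples are dropped before testing. Raw
counts, not balanced values, are tested — the NB model is a count model,
and balancing weights would destroy its sampling interpretation.
Condition-specific sets are the significant pairs split by fold-change
sign. `classify_retained_lost` labels a reference pair "lost" in a second
comparison when it is significantly reduced there (q below the FDR with
negative log2FC); reference pairs absent from the mutant universe are
reported separately and excluded from the denominator.

## Focal loop calling

The caller re-implements the donut-filter idea: for each pixel at
separation `s`, four kernels over a `(2·donut_w+1)²` window — donut ring,
lower-left quadrant, horizontal stripe, vertical stripe, all excluding the
center `(2·peak_w+1)²` peak window — estimate the local background as
(kernel sum of balanced counts) / (kernel sum of decay-expected values) ×
decay-expected at `s`. The expectation is the maximum over the four
kernels, converted to the raw-count scale by dividing by the anchor
weights, and the p-value is a Poisson upper tail on the raw count. BH runs
within separation strata (10-bin chunks) so that short- and long-range
pixels are corrected within comparable families. Called pixels must also
clear observed/expected fold filters (1.75× over donut and lower-left,
1.5× over the stripes — the conventional enrichment thresholds for this
family of callers); significant pixels merge by 8-connectivity, the summit
being the most significant pixel. Defaults: `peak_w = 1`, `donut_w = 5`,
`min_sep = 2` bins, `max_sep = 2 Mb`, FDR 10%.

The Poisson background is appropriate for a single deeply sequenced map
whose pixel noise is counting noise — the protein-directed (PLAC-seq-like)
setting the caller targets, and what the φ = 0 synthetic maps emulate. On
maps with per-pixel NB noise (φ > 0) the Poisson tail is anti-conservative
and the caller over-calls; this is inherent to the method, is visible in
the demo pipeline, and is why loop-level validation uses φ = 0 maps.
Loop-level false discovery also exceeds the pixel-level nominal rate
because each true loop contributes several significant pixels that merge
into one call while false pixels tend to be singletons.

**Anchor annotation.** An anchor is Gene if a TSS coordinate falls inside
its bin, else Enh if a distal-enhancer interval intersects it, else Un —
the precedence makes the classes mutually exclusive. "Distal" enhancers
are peaks whose midpoint is more than 2 kb from every TSS (configurable).
Expected pair-class frequencies re-draw each anchor bin uniformly within
its own chromosome (pairing preserved) and average class frequencies over
iterations; an analytic marginal-product limit (point annotations of
genomic fraction `f` give expected Gene-Gene → `f²`) is verified in tests.
Peak–loop association delegates to the permutation overlap null below.

## Permutation overlap null

The observed statistic is the fraction of query intervals with ≥ 1 bp
intersection of any target. Each iteration re-places every query element
uniformly at random within its own chromosome, preserving element lengths;
the empirical p-value is `(1 + #{null ≥ observed}) / (n_iter + 1)`. The
statistic is discrete in the number of query elements, so calibration
checks use enough elements (hundreds) that the granularity is finer than
the resolution of the uniformity test.

## Expression analyses

RPKM is `counts × 10⁹ / (length × library size)`. Differential expression
reuses the NB core; the DE set requires both q below the FDR and fold
change above the cutoff (defaults FDR 5%, 2-fold — both exposed in config,
since different comparisons in this setting have used FDR 1% and 5%).
Dependence partitioning is pure set algebra: a base DE gene is
factor-dependent when it also changes in either mutant comparison. Term
enrichment is the classic one-tailed hypergeometric per term against the
universe, with no ontology-graph propagation — term-to-gene maps are a
plain TSV.

## Clustering and embedding

Contact profiles are per-sample balanced vectors over a shared bounded-
separation universe (default max 10 Mb), depth-normalized to a common sum.
K-means (scikit-learn, seeded, best of `n_init` restarts) clusters bin
pairs; samples cluster hierarchically on `1 − Pearson` correlation with
average linkage; t-SNE (scikit-learn, PCA initialization, fixed seed)
embeds samples in 2-D. The contracts are determinism under seed and
neighbor preservation, not specific coordinates.

## Synthetic-data generator

The generator defines the conditions under which the pipeline is
validated. Defaults: two chromosomes (10 + 8 Mb), 25-kb bins, decay
exponent `α = 1` (the canonical cis contact decay regime), NB replicate
dispersion `φ = 0.1` (typical biological-replicate variability for count
assays), expected depth 2 × 10⁶ cis pairs per replicate (a deep desk-scale
library: real experiments carry hundreds of millions of pairs over a
genome ~150× larger), 2 replicates per condition, 6 TADs at 2× within-
block enrichment, 30 loops at 8× planted with non-overlapping 3×3
footprints, 10 of them differential with a 4-fold condition contrast
(multiplier 8 in condition 2 vs 2 in condition 1). Loop enrichment
multiplies the loop pixel and its immediate 3×3 neighborhood, keeping
truth labels unambiguous and loops focal. Peaks are 500-bp intervals
centered in anchor bins, present at each planted anchor with probability
0.9, over a Poisson background of 3 per Mb. Expression counts are NB
(`φ = 0.05–0.1`) over log-normal baseline means; DE genes change by
log2FC = 2 and their TSS are placed inside differential-loop anchor bins,
linking the expression and chromatin truths. Every generator output is a
pure function of (config, seed); per-operation child seeds derive
deterministically (CRC-based, stable across sessions).

Validation suites scale these conditions to their question: FDR
calibration uses a single 2-Mb chromosome (~2,300 tested pairs) and 20
null simulations; power uses planted 4-fold loops at summit means well
above 50 counts; loop-calling suites use 10-kb maps of an 8-Mb chromosome
at depth 10⁶ with φ = 0 (the protein-directed deep-map regime). A planted
differential loop counts as recovered when a significant pair lies within
one bin of its summit — the same ±1-bin convention used for loop-summit
accuracy — because the planted object is a focal 3×3 structure, not a
single pixel.

What the generator does **not** emulate: trans contacts,
restriction-fragment biases, mappability and copy-number artifacts,
compartment-scale (A/B) structure, TAD nesting, or sequence-level reads.
Passing tests therefore demonstrate the statistical machinery —
calibration, power, convergence, determinism — under the stated noise
model, not robustness to every artifact of real libraries.

## Numerical choices and degenerate inputs

- Exact-test tail sums use log-space accumulation with a `1 + 1e-10`
  tie tolerance when comparing outcome probabilities.
- `bh_adjust` propagates NaN p-values and excludes them from the family
  size.
- Fisher's odds ratio uses a Haldane 0.5 correction only when a cell is
  zero; zero-margin tables are rejected.
- Rank-sum p-values are exact (full enumeration, mid-ranks, two-sided by
  doubling the smaller tail, capped at 1) for pooled n ≤ 12, otherwise
  normal with tie-corrected variance and 0.5 continuity correction;
  all-tied samples are rejected.
- Degenerate simulations behave sensibly: depth 0 gives empty matrices,
  `peak_link_prob = 0` gives pure background peaks, empty loop sets give
  empty outputs rather than errors.
- All text outputs use fixed float formatting (`%.8g`) and stable sort
  orders, so identical seeds give byte-identical files.

## Limitations

- Only two-group designs; no covariates or GLM designs.
- The exact NB test, not the quasi-likelihood F-test; results are
  edgeR-like but not numerically identical to any specific edgeR run.
- The loop caller is single-resolution and does not merge calls across
  resolutions.
- Permutation nulls preserve chromosome assignment and element length but
  not local covariates such as GC or accessibility.
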