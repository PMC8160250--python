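# Methods

## Scope and pipeline

`coexatlas` implements a per-tissue and cross-tissue analysis of gene
co-expression: confound adjustment, signed network construction, community
detection, multiplex tissue-sharing statistics, bootstrap inference on
embedding global structure, community-based tissue classification, gene-set
over-representation, and community-conditional p-value statistics. All
stages are deterministic given their seeds, and a synthetic-data generator
with planted ground truth exercises every stage.

## Synthetic data generator

Expression for tissue t is `x_gs = sign_g·b_g·f_s + μ_g(t) + Σ_c β_gc·c_s +
ε_gs`: a per-tissue latent factor `f_s ~ N(0,1)` drives each planted block
(tissue-shared blocks share membership, not factor values, matching the
per-tissue network construction), `μ_g(t) ~ N(0, tissue_effect_sd²)` is a
tissue-specific mean signature constant across samples, confounders act
additively and linearly, and `ε_gs ~ N(0, noise_sd²)`. Two block members
with loadings `b_i, b_j` then have expected correlation
`b_i·b_j / sqrt((b_i²+σ²)(b_j²+σ²))`; the defaults `b = 0.95, σ = 0.31`
give r ≈ 0.904, i.e., Fisher z ≈ 1.49, comfortably above the 0.8 edge
threshold, which is what "well-separated" means throughout the tests.

Deliberately not modeled: RNA-seq count noise (negative binomial), library
size artifacts, and genotype-driven (eQTL) structure. Passing tests
therefore demonstrate correctness of the statistics under a linear Gaussian
factor model, not robustness to count-data pathologies; on real data the
usual variance-stabilizing preprocessing is assumed to have happened
upstream.

Gene-level p-values are a two-component mixture: nulls are Uniform(0,1),
non-nulls are two-sided normal p-values with noncentrality `effect`
(default 3, a moderately powered association), and non-null status is
assigned with sampling weight `enrichment_ratio` (default 3) inside the
community mask.

## Confound adjustment

The number of latent factors is estimated by parallel analysis: each gene's
values are permuted independently across samples (n_perm ≥ 20, default 20)
and the k-th singular value of the centered matrix must exceed the
(1 − α) quantile (α default 0.05) of the permuted k-th singular values,
counting until the first failure. The procedure named in the source
literature leaves its parameters unstated; these defaults are the package's
choice. Factors to remove are the leading left singular vectors, and
removal is per-gene OLS residualization against [intercept | covariates],
implemented via a shared QR projection. Rank-deficient designs are rejected
with the collinear columns named. This is a deliberately transparent
stand-in for full surrogate-variable analysis: it captures the
estimate-then-residualize behaviour without the iteratively reweighted
machinery.

## Network construction

Pearson correlations (zero-variance genes dropped with a warning), Fisher
z-transform with |r| clipped at 1 − 1e-15 so duplicate genes map to a large
finite z that preserves edge ordering, and a strict hard threshold:
`A_ij = z_ij` iff `|z_ij| > cutoff` (default 0.8); entries exactly at the
cutoff are dropped. A stores the signed z-weight, not |z| and not r.

## Signed-modularity Louvain

Q* is evaluated over ordered node pairs with the diagonal included; the
diagonal δ terms are constant across partitions, so move gains ignore them.
Weights enter Q* mapped into [0, 1]; the default mapping clips magnitudes
at 1 (thresholded z-weights exceed 0.8 by construction, so clipping
preserves the ranking among strong edges), with min-max rescaling available
(`mapping="rescale"`). Resolution γ multiplies the expected-weight terms
(default 1).

The optimizer is two-phase Louvain from singletons with three
implementation details that matter:

- Candidate moves include, besides neighbor communities, (a) one empty
  community (a node held only by negative edges may be best off alone) and
  (b) every community carrying negative strength whenever the moving node
  has negative strength — the expected-negative-weight term `e−` can favor
  co-placing nodes that share no edge, and restricting candidates to graph
  neighbors misses those optima.
- Ties are broken toward staying put, then by shuffled candidate order
  (seeded), so every accepted move strictly increases Q* and the procedure
  terminates.
- After the aggregation loop converges, a Kernighan–Lin-style escape pass
  tentatively moves every node once to its best alternative (even when the
  step is negative) and rolls back to the best prefix; an accepted escape
  restarts the main loop (up to 8 attempts). This crosses barriers such as
  three-way merges whose pairwise steps are each negative, which plain
  greedy Louvain cannot. On exhaustively enumerable signed toys (≤ 8 nodes)
  the search attains the global optimum in ≥ 95% of seeds.

Convergence tolerance is 1e-10 of Q* per pass. Communities below `min_size`
(default 4 genes) are dropped from the atlas; their genes become
community-less.

## Multiplex statistics

The gene universe of a multiplex is restricted to genes in at least one
layer's retained communities; genes absent from a layer receive a per-gene
sentinel membership there and can never co-cluster. π_k is estimated over
pairs with positive index (an option includes k = 0 over all universe
pairs). Maximal groups are connected components of the gmi = L graph;
components that are not cliques are split into maximal cliques, because
"always in the same community" is a pairwise-all property. Interlayer
coupling is implicit (each gene linked to itself across layers) and never
enters the computation, which needs only memberships.

## Embedding persistence

The inter-cluster distance d(i, j) is not prescribed by the statistics
themselves; the package uses the Euclidean distance between cluster
centroids in embedding space (cheap and stable), with medoid and
average-linkage options. Bootstrapping draws ⌊0.8·n⌋ rows without
replacement per replicate (the operational description of drawing from 80%
of the data points); classical with-replacement resampling is available via
`replace=True`. A tissue absent from a subsample yields NaN rows handled
pairwise downstream.

The variance of the bootstrapped distance estimator is the unbiased sample
variance by default. The published mixed-denominator form
`Σd²/(B−1) − (Σd/(B−1))²` is dimensionally inconsistent as a variance (it
does not vanish for constant replicates); it is retained verbatim behind
`summarize_distances(..., verbatim=True)` for auditability.

The conservation test uses Spearman correlation by default because the
variance factor 1.06/(n−3) in the test statistic is the
Fieller–Hartley–Pearson correction for Spearman's rho; Pearson is a flag.
The profiles correlated for a pair (i0, i1) exclude i0 and i1 themselves
(their zero self-distances would inflate C), and the n entering the
statistic is the number of tissues in the profiles — the sample size of the
correlation — rather than the total tissue count; with the total count the
statistic would be inflated by sqrt((L−3)/(L−5)) and the test would be
anticonservative. Type-I error calibration at α = 0.05 is verified by
simulation (30-tissue null profiles, 2,000 replicates). For tissue sets the
coefficient is the minimum over pairs (first order statistic), reported
with that pair's test.

UMAP runs with `random_state` set, which forces single-threaded, fully
deterministic output; a linear PCA backend is provided for settings where a
fast deterministic embedding suffices (several tests use it), and any
callable `samples × features → samples × 2` can be plugged in.

## Tissue prediction

Positive-class F1 (not macro-averaged) of `SVC(kernel="linear",
class_weight="balanced", C=1)` under seeded stratified 3-fold CV; the
"can predict" rule is strict (F1 > 0.80 exactly at the threshold is a
negative). C = 1 is the classifier default, recorded in the report; the
choice is not sensitive on separable communities.

## Enrichment

Upper-tail hypergeometric p per gene set (sets intersected with the
background first), BH-adjusted per community (a global-family option
exists). The background universe defaults to all genes of the analyzed
expression matrices and is configurable. Communities with fewer than four
genes are reported "not enriched" regardless of overlap.

## π1 and FDR

π0 is estimated Storey-style: `π0(λ) = #{p > λ}/((1−λ)m)` over
λ ∈ {0.05, …, 0.95}, with a cubic polynomial in λ extrapolated to λ = 1 and
clipped to [0, 1]. The estimator is unbiased in simulation across true
π1 ∈ {0, 0.2, 0.4, 0.6} (|bias| < 0.05 at m = 20,000, effect 3); at
m ≈ 2,000 its sampling standard deviation is roughly 0.09, so single-run
estimates on small gene sets should be read with that noise in mind. At
least 100 p-values are required. Exact-zero p-values are floored at the
smallest positive float before −log10. FDR(p) uses the empirical cdf and
F0(p) = p. A Bonferroni threshold over the community stratum is reported as
a reference line only.

## Master matrix and formats

Per-tissue genes × samples TSV (or GCT 1.2) with duplicate gene ids dropped
on read; the master matrix is samples × union-of-genes with per-gene
min-max scaling to [0, 1] over the pooled samples (per-gene rather than
global so every gene spans a comparable range in the embedding; a flag
switches) and zeros where a gene is absent from a tissue. Constant genes
scale to 0.

## Problem sizes in the shipped tests

The suite verifies the planted-structure claims at sizes chosen to make the
statistics stable while keeping the default run fast: closed-form
correlation convergence at n = 2,000 samples, partition recovery at n = 500
samples per tissue, the 13-layer multiplex at 60 samples per layer and 30
genes, calibration at 2,000 replicates, and π1 recovery at m = 20,000
p-values. The end-to-end demo uses three tissues of 30 samples with 40
genes.

## Known limitations

- The parallel-analysis + SVD residualization stand-in is not the full
  iteratively reweighted surrogate-variable algorithm; heavily structured
  confounding correlated with the planted signal may be over- or
  under-corrected.
- Maximal-clique splitting of non-clique gmi components is exact but
  exponential in the worst case; it is intended for the small components
  that arise in practice.
- The conservation test's normal approximation assumes independent profile
  entries; distance profiles of nearby tissues are mildly dependent, so
  p-values for strongly overlapping sets are approximate.
- Louvain optimality is only guaranteed empirically (≥ 95% on enumerable
  toys); large networks inherit the usual local-optimum caveats of
  modularity maximization.
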