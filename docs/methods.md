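# Methods

## The analysis model

The pipeline treats a variance-stabilized expression matrix (genes ×
samples, log-like scale) as its primary input and makes three modeling
commitments:

1. **Co-expression is pairwise Pearson correlation**, and the network is the
   graph of gene pairs with |r| strictly greater than a hard threshold
   (default 0.90). No soft-thresholding or topological-overlap transform is
   applied; the threshold is strict because the decision rule is "greater
   than", and genes isolated after thresholding are excluded from the
   reported network so that "nodes" means connected genes. Correlation can
   be computed in row blocks for memory control; results are independent of
   block size, and matrices with missing values fall back to
   pairwise-complete estimation.

2. **Modules are Markov-cluster (MCL) clusters.** MCL alternates expansion
   (squaring the column-stochastic transition matrix) and inflation
   (entrywise power, default 1.8, then column renormalization), pruning
   entries below 1e-5 and renormalizing, until the matrix changes by less
   than 1e-6 or 200 iterations (non-convergence is an error carrying the
   residual). Edge weights entering MCL are |r| — edges are retained by
   absolute correlation, and MCL requires nonnegative input — and every node
   receives a self-loop of weight 1 (standard regularization guaranteeing
   aperiodicity). Clusters are read from attractor rows of the limit matrix;
   attractors with overlapping support form one attractor system, each node
   joins the system holding most of its limiting column mass, and exact ties
   go to the system whose smallest member sorts first, making the output
   deterministic. Module labels are assigned by decreasing size with ties
   broken by the lexicographically smallest member id; the numbering is
   reproducible but carries no meaning beyond size order.

3. **A module's phenotype link is its eigengene.** The eigengene is the
   first right singular vector of the module's gene-standardized submatrix
   (unit norm over samples); genes are standardized first so no
   high-amplitude gene dominates. The principal-component sign is free, so
   scores are oriented to correlate nonnegatively with the module's mean
   standardized profile; when that mean profile is constant (possible for a
   two-gene perfectly anti-correlated module) the first nonzero score entry
   is made positive instead — an arbitrary but deterministic convention.
   Eigengenes are screened against traits by Spearman correlation with
   average ranks for ties; the p-value is an exhaustive permutation tail for
   n ≤ 9 untied observations and the t approximation otherwise. A module is
   selected for a variable iff |ρ| > 0.7 and Bonferroni-adjusted p < 0.05,
   with family size m = (#modules) × (#variables). The genotype × nitrogen
   interaction is screened separately as the product of centered binary
   codings (orthogonal to both main effects in a balanced design) and is
   not counted in the default Bonferroni family; a caller who wants it
   inside the family can pass `bonferroni_m` explicitly.

## Differential expression surrogate

DEG selection is a deliberate stand-in, not a count model: per gene, a Welch
two-sample t-test between nitrogen levels on the transformed values within a
(genotype, segment) cell, BH adjustment across genes, and the conjunction
rule |mean difference| > 1 (strictly) with adjusted p < 0.05. Direction
"up" means higher expression at 270 mg N kg⁻¹. With three replicates per
side this test is conservative relative to a shrinkage-based
negative-binomial fit; DEG counts are therefore treated as descriptive
output, not a validated quantity. The cross-contrast DEG union (the network
input set) is far better powered than any single contrast: at a 6 SD latent
shift, union recovery of planted nitrogen-responsive genes averages ≈ 94%,
while single-contrast recovery is ≈ 30%.

## Null-model comparison

The observed graph is compared to three ensembles — Erdős–Rényi G(n,p),
Watts–Strogatz (ring degree k, rewiring β), Barabási–Albert (attachment m) —
matched to the observed node count. For each candidate parameter, replicate
graphs are drawn, adjacency eigenvalues are scaled by 1/√n and smoothed with
a Gaussian kernel (Silverman's rule; bandwidth floored at twice the grid
spacing so near-degenerate spectra remain resolvable) on a grid covering the
pooled support, and KL(observed ‖ ensemble-mean density) is integrated by
the trapezoid rule with a 1e-12 density floor. The KL direction and floor
are package choices, documented here because the underlying method family
leaves them open. Default grids: ER p at five multiples (0.6–1.6×) of the
observed edge density; WS k at the nearest even mean degree with β on a
five-point log grid from 0.01 to 1; BA m from 1 to 6. The best model is the
argmin of the per-model minima. Self-consistency holds: at n = 300 with 10
replicates per grid point, the generating model is recovered in 20/20 trials
for each ensemble (acceptance suite).

## Hubs and enrichment

Betweenness is unweighted shortest-path (Brandes) centrality with
undirected pair counting (each unordered pair once, no normalization); hub
calls depend only on ranks and are invariant to the normalization
convention. A hub must lie in the top decile of both degree and
betweenness; the threshold is the score of the ⌊f·n⌋-th ranked node and all
ties at the threshold are kept, so degenerate graphs (regular rings) can
have more than f·n hubs — conservative by construction. Both a global scope
and a per-module scope (induced subgraph) are provided; per-module is the
default for module reports.

GO overrepresentation is the classic one-sided Fisher/hypergeometric
upper-tail test per term with BH across terms within a gene set; no
GO-graph decorrelation is attempted. The universe defaults to the analyzed
gene set (network genes for module enrichment) and is configurable, since
universe choice is a genuine degree of freedom. TAP-family composition uses
an exact binomial upper tail per family against supplied background
frequencies and always reports the exact observed proportion.

## Synthetic data: what it emulates and what it does not

The generator emulates a 2 × 2 × 4 factorial with replicates. Each planted
module has a latent profile: a centered contrast coding of its driver
(genotype, nitrogen, segment gradient, or genotype × nitrogen product)
scaled by the effect size, plus unit Gaussian sample noise, standardized to
mean 0 / SD 1. Genes load on the latent with coefficients uniform in
[0.7, 1], all-positive unless the module is declared signed (random signs
then produce anti-correlated members, which the |r| network must handle).
Per-gene noise is set to a·√(1/ρ − 1) so the expected pairwise correlation
equals the requested ρ for every gene pair regardless of loadings;
empirically the mean within-module |r| lands within ±0.01 of the target at
n = 48. Traits are linear in the latents plus Gaussian noise, with the
closed-form attenuation cor = λ/√(λ² + σ²) used to dial population
correlations. Annotation terms are Bernoulli background (default rate 0.05)
with planted terms covering ≥ 80% of a chosen module.

Defaults define the simulated study: 3 replicates (48 samples), eight
planted modules (two nitrogen-driven, two genotype-driven, one
segment-driven, one interaction-driven, one trait-only, one null; 10–40
genes each), within-module correlation 0.95, driver effect size 6 SD —
chosen to mimic strong two-fold responders that a replicated design detects
confidently — plus 300 unstructured noise genes. Gaussian noise on a
variance-stabilized scale is an assumption: real VST data have
mean-dependent residual variance, outliers, and correlated library effects
that this generator does not model. Passing recovery tests therefore
demonstrates correctness of the pipeline's logic under its stated model,
not robustness to real-data pathologies. Two same-driver modules share
nearly collinear latents and are expected to merge into one network module;
this mirrors real co-expression behavior and is visible in the worked
example.

## Numerical choices and degenerate inputs

- Filtering removes a gene when missing fraction > 0.5 OR variance is zero
  (the OR reading matches the referenced quality-control behavior);
  filtering is idempotent, and removing every gene is an explicit error.
- Correlation requires ≥ 3 samples and raises naming the first
  zero-variance gene.
- Exactly-threshold correlations (|r| = 0.90) produce no edge.
- An effect of exactly 1.0 is not a DEG (strict inequality).
- Constant trait variables yield undefined ρ; they are flagged and never
  selected.
- MCL on an empty graph returns an empty partition; an isolated node forms
  a singleton module.
- Spectral densities are renormalized to integrate to 1 (trapezoid,
  ±1e-6); KL is clipped at 0 to absorb negative rounding of order 1e-16.
- All generators and fits are deterministic given a seed; the pipeline
  manifest reproduces byte-identically under a fixed configuration.

## Problem sizes in the test and acceptance suites

Recovery and self-consistency checks run at the simulated study's scale
(48 samples, tens-of-genes modules) and at n = 300 nodes for null-model
selection with 10 replicates per grid point and 20 trials per ensemble;
the acceptance script additionally fits a 1109-node preferential-attachment
graph (the reference network's size) with 8 replicates. These sizes give
stable Monte-Carlo estimates while keeping the suites fast.

## Known limitations

- The Welch surrogate understates single-contrast DEG power relative to
  negative-binomial shrinkage estimators; absolute DEG counts are not
  comparable to count-model output.
- Hard |r| thresholding discards weaker co-expression entirely; no
  signed-network or soft-power analysis is provided.
- Fisher enrichment ignores GO-term dependence (no elim/weight
  decorrelation), so nested terms can co-flag.
- The module numbering of any particular external study is not
  reconstructible; only size-ordered labels are meaningful.
- The binomial TAP composition test conditions on the total TAP count and
  assumes independent family draws under the null.
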