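# Methods

## Model and assumptions

The package quantifies evolutionary rate covariation between genes on a
fixed, rooted master species tree.  Its working assumptions:

* **Congruent topologies.**  Every gene tree equals the master topology
  restricted to that gene's species set.  Branch lengths are the gene's
  own (substitutions/site); topology conflicts are rejected at load (or
  dropped on request) because the path index and the per-pair pruning
  contract both presuppose a shared coordinate system of master-tree
  nodes.  No attempt is made to reconcile discordant gene trees.
* **Rooted-as-written trees, 2|S|−2 edges after pruning.**  A root of
  degree 2 is retained in storage.  When pruning to a species set S
  leaves the root unary, the root is suppressed and the two root-adjacent
  paths merge into one edge, so a pruned binary topology has 2|S|−2
  edges.  This count is the `n` of the Fisher transform; the convention
  is a documented design choice, fixed so `n` is unambiguous.
* **Branch lengths decompose multiplicatively** into a branch effect
  (shared divergence), a gene effect (average rate), and branch×gene
  residual variation; the residual is where the biology of interest
  (shifts in selective pressure) lives.

## Relative evolutionary rates

For each pruned topology, the expected tree is fit by an alternating
averaging scheme: initialize μ_e as the mean observed length of edge e;
iterate c_g ← mean_e(l_ge/μ_e), μ_e ← mean_g(l_ge/c_g) for a fixed 2
rounds (deterministic); normalize so mean(c)=1.  The fit is NaN-aware:
every gene that observes an edge contributes to it, and edges observed by
fewer than `min_genes` (default 5) genes are flagged unusable.  Edges
whose fitted expected length falls below `min_length` (default 1e-3
substitutions/site) are likewise flagged: such branches are essentially
unresolved, carry no rate information, and would otherwise form a
degenerate low end of the mean-variance trend (their residuals are
near-deterministically zero, which leaves a spurious positive
|residual|-vs-fitted rank trend after weighting).

Residual modes:

* **uncorrected** — per-gene no-intercept OLS of lengths on μ;
  residuals l − ĉμ.  These are heteroskedastic by construction under
  multiplicative variation and reproduce the behaviour of correlating raw
  rate residuals.
* **corrected** (default) — square-root transform of both lengths and μ,
  then an iteratively reweighted no-intercept regression: weights are the
  reciprocal of a mean-variance trend obtained by sorting fitted values
  into 10 equal-count bins, taking each bin's mean squared residual, and
  interpolating linearly between bin centers (floored at 1e-8 of the mean
  bin variance); 2 reweighting rounds; the final weighted residuals are
  standardized to unit variance per gene.  Exact proportionality (maximum
  absolute residual below 1e-12 of the response scale) short-circuits to
  all-zero residuals so float-epsilon noise is never amplified by the
  weights.

Knobs: `transform` (sqrt/none via `corrected`), `n_bins` (10),
`reweight_iters` (2), `min_genes` (5), `min_edges` (5), `min_length`
(1e-3).  Corrected residuals are invariant to a global rescaling of all
branch lengths.

Whether RERs should be computed once per gene on its full species set or
per pair on the shared intersection is genuinely open; this package
computes them per unique intersection (cached by species-set key), which
matches the pruning contract exactly at the cost of recomputing residuals
for genes that participate in many distinct intersections.

## All-pairs ERC

For each gene pair: shared species S (pairs with |S| < `min_species`,
default 10, are skipped with a coded reason — the transform needs n > 3
and small intersections give unstable correlations); pruned edges from
the path-index cache; RER vectors (cached per gene × species-set key);
Pearson r; FtERC = arctanh(r)·√(n−3) with n the usable edge count.
Correlations with |r| ≥ 1−1e-12 are clamped (flagged and counted) rather
than emitted as infinities.  Pairs are grouped by shared-species key and
merged in deterministic key order, so results are independent of thread
count; matrices are stored float32 with NaN for missing pairs, never
zero-filled.

## Downstream consumers

* **Z-scores** use each gene's own row distribution (mean/sd with ddof=1
  over non-missing partners, self excluded; at least 30 partners
  required).  Hit–hit edges in query networks use the max of the two
  endpoints' row-wise Z — the symmetric choice; the alternative (min or
  query-row-only) is stricter but arbitrary in the same way.
* **Clustering null**: global clustering coefficient (3×triangles /
  connected triples) against uniform G(n, m) random graphs with matched
  node and edge counts; empirical p = (1 + #{null ≥ observed})/(1 +
  n_random).  Degree-preserving rewiring is available as an option for
  networks whose degree sequence is very skewed.
* **Elastic-net annotation models**: features are the gene's FtERC row
  with missing values imputed at 0 — the null expectation of the
  statistic, which makes the imputation neutral rather than informative —
  and the self entry removed the same way.  Columns are standardized
  (population sd); the regularization path has 100 log-spaced values from
  the smallest penalty that zeroes all coefficients (computed as
  max|Xᵀ(y−ȳ)|/(n·α), verified against the reference R implementation)
  down by 1e-4.  Stratified 10-fold CV, AUC averaged across folds (not
  pooled); the 1-SE rule picks the strongest penalty whose mean AUC is
  within one standard error of the best.  Reported coefficients are refit
  on all data at the 1-SE penalty and destandardized, so an all-zero raw
  feature row scores logistic(intercept).  The saga solver runs at
  tol=1e-3 with a 100-iteration cap and warm starts along the path; the
  residual coefficient slack does not move CV AUCs at these problem
  sizes.

## Synthetic data

The generator emulates the four features of real comparative tree sets
the pipeline is sensitive to: per-gene species missingness, gene-specific
average rates, branch-specific rate shifts shared within co-functional
modules, and multiplicative noise:

    l_gb = t_b · r_g · exp(σ_shared·f_{m(g),b} + σ_noise·ε_gb)

with t the master branch lengths, r_g log-normal(meanlog 0, sdlog 0.5 —
roughly a three-fold spread of average rates), f a per-(module, branch)
standard-normal latent factor (absent for null genes) and ε independent
standard normal.  Multiplicative log-normal noise is chosen deliberately:
it makes raw branch lengths heteroskedastic (variance growing with the
mean), so the corrected/uncorrected comparison tests something real.
Species are dropped independently per gene (probability p, either fixed
or drawn per gene from a uniform range) and the tree restricted with path
lengths summed, so congruence holds by construction.

Default ("reference") conditions: a birth-death master tree (birth 1.0,
death 0.4) with 50 extant species rescaled to total length 10
substitutions/site — a yeast-like divergence scale — 200 genes, 4 modules
of 10, σ_shared = 0.5, σ_noise = 0.3, p = 0.1.

What the generator does **not** emulate: topology discordance,
correlated (phylogenetically clustered) missingness, sequence-level
estimation error in branch lengths, rate variation along a branch, or
module overlap.  Passing tests therefore demonstrate correctness of the
computations and calibration/power under the stated generative model,
not performance on real genomes.

## Study conditions used by the tests and the acceptance script

* **Null calibration** (FtERC mean/sd): 200 independent genes, 50
  species, missingness 0.1.  Note a mechanical finite-size effect: with G
  genes, each gene participates in the expected tree, coupling any two
  genes' residuals at ≈ −1/G; the Fisher scaling amplifies the resulting
  mean pairwise score to ≈ −√(n−3)/G.  At G = 200 this is ≈ −0.04 (the
  measured value); at genome scale (G ≈ 10⁴) it is negligible.
* **Variance stabilization** (per-quintile sd ratios of FtERC vs raw r):
  requires branch counts spanning roughly 20–200, which homogeneous 10%
  missingness on 50 species cannot produce (n concentrates near 79, and
  the raw-Pearson sd ratio is then mechanically ≈ 1.1).  The calibration
  preset therefore uses 110 species and per-gene missingness drawn from
  U(0.05, 0.9), 200 null genes.
* **Residual-trend removal**: 200 genes, 50 species, no missingness; the
  reported quantity is the magnitude of the mean (over genes) Spearman
  correlation between |residual| and fitted value.  The mean of
  *absolute* per-gene correlations has a hard null floor of
  E|ρ̂| ≈ 0.8/√n ≈ 0.08 at n = 95 branches and is therefore not a usable
  criterion; the signed mean averages sampling noise out while any real
  trend survives.
* **Discrimination AUC** (corrected vs uncorrected): 10 replicates of
  100 genes (4 modules of 10 + 60 null genes), 50 species, p = 0.1;
  within-module pairs vs both-null pairs scored by FtERC.
* **Annotation recovery**: the reference conditions; each simulated
  module serves as a pseudo-annotation; shuffled controls draw random
  10-gene sets.
* **Network recovery**: queries are 4 members of one module at Z ≥ 3;
  the clustering null uses 10,000 random graphs.

With ~40% of genes in modules the expected tree absorbs a small share of
the module factors, which inflates null-pair scores slightly and
deflates cross-module pairs; the effect shrinks with the module fraction
and does not change any corrected-vs-uncorrected comparison, since both
modes share the expected tree.

## Numerical choices

* Canonical node numbering (children sorted by smallest descendant leaf
  label) makes isomorphism a direct array comparison and all outputs
  byte-deterministic; Newick is written with 10 significant digits.
* Fisher clamp at |r| = 1−1e-12; branch counts n < 4 are a hard error.
* Ties in the variance-trend bins are resolved by stable argsort; bin
  count degrades gracefully to ⌊edges/2⌋ for short vectors.
* Zero-length branches on input are treated as observed zeros (missing
  means an absent species, never a short branch); the `min_length`
  filter, not the parser, decides whether they are usable.
* Thread parallelism (joblib threading backend over species-set groups)
  affects wall time only; merges are ordered by species-set key.

## Known limitations

* Incongruent gene trees are rejected, not reconciled; datasets with
  substantial discordance need external reconciliation first.
* The expected tree is refit per species intersection from all genes
  observing each edge; with very few genes (< ~30) the −1/G residual
  coupling noted above becomes visible in null score means.
* The elastic-net feature space is the FtERC row itself, so predictions
  for genes absent from the matrix require externally computed rows
  aligned to the model's feature genes.
* No per-pair p-values are produced; FtERC and row-wise Z-scores are the
  intended effect sizes.
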