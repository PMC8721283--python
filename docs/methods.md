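# Methods

This note documents the statistical procedures atlaskit implements, the
assumptions behind them, the synthetic data generators used to exercise
them, and the numerical choices made where the design was genuinely open.

## Shared primitives (`atlaskit.stats`)

**BH correction.** `bh_adjust` is the Benjamini-Hochberg step-up: with
ordered p-values `p_(1) <= ... <= p_(m)`, the adjusted value is
`min_{j >= i} p_(j) * m / j`, clipped to [0, 1]. It is implemented directly
(five lines) and cross-checked against statsmodels in the test suite.

**MAD-outlier test.** `mad_outlier_upper` converts each value to a robust
z-score, `z_i = (v_i - median(v)) / (1.4826 * MAD(v) + eps)`, and refers it
to a Student-t with `n - 1` degrees of freedom, one-tailed upper. Reading
the robust z as a t statistic is a pragmatic choice (the robust z is not
exactly t-distributed at small n); a standard-normal reference is exposed
via `reference="normal"`. The `eps = 1e-9` floor handles the degenerate
`MAD = 0` case: values at the centre keep `p = 0.5`, anything strictly
larger becomes an extreme outlier. This preserves the test's intent
without dividing by zero. BH correction is applied across the tested
items and flags are `q < alpha`.

**Rank tests.** `mann_whitney` uses midranks for ties; p-values come from
exact enumeration of all group assignments when `n_a + n_b <= 10` and from
the normal approximation with tie and continuity corrections otherwise
(the asymptotic branch delegates to scipy). With heavy ties the continuity
correction can differ from the exact answer by more than 0.02; on
continuous data the two agree closely by n = 8 per group.
`marker_genes` runs one-vs-rest rank-sum tests per gene per cluster with
BH within cluster; the reported fold change is
`log2((mean_in + 1) / (mean_out + 1))` on normalized expression — the
pseudo-count of 1 stabilises low-expression genes and is a convention, not
part of the test statistic. Clusters with fewer than two cells are skipped
with a warning. Whether one-vs-rest or pairwise contrasts are preferable
is context-dependent; one-vs-rest is the default used throughout.

## QC and normalization (`atlaskit.qc`)

Cells are kept when their detected-gene count (genes with count > 0) lies
in [200, 2500] and their mitochondrial count share (genes prefixed `MT-`)
is strictly below 30% — the boundary fails. Genes must then be expressed
in at least 3 retained cells. Cell filters are applied before the gene
filter so gene prevalence reflects retained cells; because removing rare
genes can in turn push a cell below the detected-gene floor, the
cell-then-gene round is **iterated to a fixpoint**. This makes `qc_filter`
idempotent and guarantees the returned matrix satisfies every threshold
simultaneously; the `QCReport` accumulates deduplicated removal counts
(gene-count bounds first, mito among the survivors) so that
`n_in - removals = n_out` always holds.

`median_normalize` scales each cell to the median of the pre-scaling
totals and also returns the `log1p` transform; it preserves within-cell
expression proportions exactly and refuses zero-total cells.

`select_hvg` is the classic binned-dispersion recipe: per-gene mean and
dispersion (variance/mean) on the back-transformed `expm1` values, the
mean carried on the log1p scale for the range thresholds
(`0.0125 <= mean <= 3`), dispersions z-scored with plain mean/sd within 20
equal-frequency mean bins, and selection at normalized dispersion >= 0.5.
Bins collapse gracefully when there are fewer distinct means than bins.

## Cluster-level doublet flagging (`atlaskit.doublets`)

Doublets concentrate in small hybrid clusters with elevated per-cell
doublet scores, so the test operates on clusters, not cells: compute the
median doublet score per cluster, run the MAD-outlier test (upper tail
only — doublets have high scores) across the vector of cluster medians,
BH-correct, flag clusters at `q < 0.1` and propagate the flag to their
cells. The operation takes any supplied clustering; producing the
clustering itself (e.g. by iterative sub-clustering) is out of scope, which
cleanly separates the statistic from the third-party clusterer. Under a
global null (i.i.d. scores) the measured per-cluster false-flag rate at
`alpha = 0.1` is ~3%.

## Cell-type similarity / label transfer (`atlaskit.transfer`)

The classifier is multinomial logistic regression with an L2 (ridge)
penalty, minimizing

    (1/N) * sum_i -log P(y_i | x_i) + (lambda/2) * ||B||_F^2

with unpenalized intercepts, over a 50-point log-spaced grid spanning four
decades below a data-derived `lambda_max`. Because no finite ridge penalty
drives coefficients exactly to zero, `lambda_max` follows the glmnet
convention: the lasso gradient bound `max |x_j . (y_c - pi_c)| / N`
inflated by 1000. Ten stratified CV folds give the mean held-out deviance
and its standard error per grid point; the **one-SE rule** selects the
largest penalty whose deviance is within one standard error of the
minimum, and the model is refit on all data there. Fits are lbfgs,
warm-started along the descending path (path tolerance 1e-4, final fit
1e-6).

`transfer_probabilities` builds the feature space as the reference's HVGs
intersected with the query's genes (>= 50 required) on median-normalized
log expression, standardized gene-wise **independently** within reference
and query (constant genes map to zero, so a class-uninformative constant
gene cannot influence the fit). Across the 50 iterations only the CV fold
assignment is reseeded (`seed + i`) — the source of variation across
iterations is otherwise unspecified in common practice, and fold
reshuffling is the minimal choice; the model is refit on the full data at
each iteration's selected penalty and the query probabilities are averaged
elementwise, so rows still sum to 1.

`call_similarity` computes the median probability per (query cluster,
reference class), runs the MAD-outlier test **across query clusters within
each reference class** (which clusters stand out for a given label — the
alternative, across classes within a cluster, answers a different
question), applies BH jointly over all (cluster, class) pairs (more
conservative than per-class adjustment; switchable with `joint_bh=False`),
and calls a pair significant only when `q < 0.05` **and** the median
probability exceeds 50%.

A caveat found during development: when the reference contains two
clusters with identical distributions, the fitted coefficient difference
between them is a sampling-noise direction, so individual cells can show
a large gap between the two probabilities even out of sample; the
cluster-level **medians** — the quantity the significance call consumes —
remain symmetric to ~0.02.

## Gene-set scoring (`atlaskit.scoring`)

`module_score` bins all genes into 25 equal-frequency bins by mean
expression and, per set gene, samples 50 control genes from its bin
without replacement (seeded); the score is the mean over set genes minus
the mean over the deduplicated control pool, per cell. It is linear in the
expression matrix by construction.

`auc_score` ranks each cell's genes descending (ties broken by a seeded
random permutation; a deterministic by-index alternative via
`tie_break="index"`), takes the top `T = ceil(0.05 * n_genes)` ranks,
forms the recovery curve `y(r)` = number of set genes at rank <= r, and
normalizes `sum_{r<=T} y(r)` by its maximum — the set (at its realized
size after intersection with the matrix) occupying the top ranks. The 5%
top fraction is the customary default for this score. Being rank-based,
the score is invariant under any strictly monotone per-cell transform.

`compare_scores` uses the two-sided Mann-Whitney test for two groups and
Kruskal-Wallis for more; empty groups are dropped.

## Receptor-ligand permutation test (`atlaskit.interactions`)

For ordered cluster pair (A, B) and gene pair (L, R), the score is
`(mean L in A + mean R in B) / 2`, reported only when L is expressed
(count > 0) in >= 30% of A's cells **and** R in >= 30% of B's cells — the
threshold is applied to both partners. The null comes from shuffling the
cluster label vector; one seeded shuffle set is shared by all pairs in a
run so results are jointly reproducible. The p-value uses the add-one
convention `(1 + #{null >= obs}) / (n_perm + 1)`, guaranteeing `p > 0`
with minimum `1/(n_perm + 1)` — a deliberate divergence from tools that
report the raw proportion (which can return p = 0). Only single-gene
pairs are supported; multi-subunit complexes (min-of-subunits) are not.

## Spatial colocalization (`atlaskit.spatial`)

Spot-level cell-type scores come from the same ridge label-transfer
machinery with spots as query cells (a substitution for anchor-based
transfer that keeps the pipeline self-contained; the output contract —
probabilistic scores summing to 1 — is the same). The colocalization
statistic builds each spot's neighborhood as itself plus its k = 5 nearest
neighbors by Euclidean distance (k + 1 values; exact distance ties broken
by spot index, which makes lattice data deterministic but sensitive to
coordinate jitter — generic coordinates are tie-free). Within each
neighborhood, Pearson correlation between the feature (a gene's
expression or a two-gene module score) and the class score; neighborhoods
with an all-zero feature or a constant vector are excluded; the statistic
is the mean over the remainder, and is missing when the feature is
uniform across all spots or nothing survives exclusion. Negative values
are masked only in the per-spot map used for plotting, never in the
returned mean.

## Deconvolution and survival (`atlaskit.survival`)

`nnls_deconvolve` solves `min ||W^(1/2)(S x - b)||^2, x >= 0` per sample
over the shared gene space (scipy NNLS) and renormalizes to the simplex;
signatures are per-class means of linear expression. This is a plain
reference-profile regression — multi-subject variance weighting schemes
are not reproduced, but the per-gene `weights` hook accepts
inverse-variance weights. All-zero solutions are flagged undefined rather
than renormalized.

`stratify_quartiles` uses linear-interpolation quantiles with inclusive
boundaries (`>= q75` high, `<= q25` low). `km_estimate` is the
product-limit estimator over distinct event times with censored subjects
leaving the risk set after their time; `logrank_test` accumulates the
hypergeometric observed-minus-expected and variance per event time and
refers `(sum(O - E))^2 / sum(V)` to chi-square with 1 df. No tie
correction beyond the aggregate `d_i/n_i` treatment is applied. Both are
cross-checked against lifelines in the tests.

## Synthetic data (`atlaskit.synthetic`)

The generators provide every input the pipeline consumes, with the
statistical structure the stages assume.

**Atlas.** Counts are negative binomial with mean `m_cg * f_i` and shared
dispersion `theta = 2` (variance `m + m^2/theta`); per-cell library
factors `f_i` are log-normal with sd 0.3. Per-gene base means are
log-normal across genes (median 0.5, sd 1 log-unit): real transcriptomes
span orders of magnitude in mean expression, and the mean-binned HVG
z-score degenerates if all genes share one mean (the bins holding the
planted markers would contain nothing else). Each of the 5 clusters (200
cells each by default) gets a disjoint block of 30 marker genes at 4x the
base mean. Each cell is independently a doublet with probability 0.08;
doublet counts are the sum of two singlet parents from different
clusters, and by default doublets form their own planted cluster (the
alternative — hiding them in a parent's cluster — is switchable). Doublet
scores are Beta(8, 2) for doublets and Beta(2, 8) for singlets: the
distributions overlap enough that per-cell thresholding would be
unreliable, which is the regime the cluster-level test is for. Ten
`MT-`-prefixed genes behave as ordinary genes; `mito_high_fraction` can
inflate a subset of cells' mitochondrial share for QC tests. A separate
`structure_seed` fixes the gene-mean landscape so that independent draws
with different `seed` values come from the *same* generative model with
fresh noise.

**Spatial grid.** Spot expression is `sum_c p_c(x, y) * profile_c` plus
zero-truncated Gaussian noise (sd 0.1 in count units), where the
`profile_c` are the atlas cluster mean-count profiles and the proportion
fields `p_c` are spot-wise normalized non-negative weight fields on a
20 x 20 grid. The default layout mimics tissue sections in which a
dominant structural compartment fills most of every spot: the last
cluster carries a constant weight of 10 (~73% of each spot), cluster 0 a
cosine field varying only along x, cluster 1 one varying only along y,
and the rest Gaussian bumps. The dominance is load-bearing: proportions
on a simplex are negatively coupled at roughly `-p/(1-p)`, so with five
equal clusters any two fields would show a spurious neighborhood
correlation near -0.25; with minor fractions the coupling drops to ~-0.1,
below the noise floor of the statistic. With this layout a strongly
expressed marker of cluster 0 recovers its own field at mean r ~ 0.6 and
shows |r| ~ 0.1 against cluster 1's independent field.

**Cohort.** Per-sample proportions are Dirichlet(2, ..., 2); bulk
expression is the proportion-weighted mixture of cluster profiles with 5%
multiplicative Gaussian noise; event times are exponential with rate
`0.1 * exp(beta * p_hazard)` and censoring is independent exponential at
rate 0.05 (~75% events at n = 400 samples). The default `beta` is
calibrated analytically so the hazard ratio between the top- and
bottom-quartile strata of the hazard cluster's proportion is 2: under the
Dirichlet prior that proportion is marginally Beta(a, A - a), the
expected gap between the upper- and lower-quartile conditional means is a
truncated-Beta integral, and `beta = log(2) / gap`
(`quartile_hazard_coefficient`). A fixed per-unit coefficient would make
the planted between-strata effect depend on the prior's spread, which is
not the quantity of interest.

**What the generators do not emulate** — and hence what passing tests do
not establish about real data: ambient RNA and empty droplets, batch
effects, realistic gene-gene correlation beyond cluster structure,
mean-dispersion trends, spatial segment boundaries or histology-aligned
coordinates, and cohort covariates or informative censoring. The
generators validate the *statistical machinery* (calibration, power on
planted effects, oracle agreement), not biological discovery.

## Problem sizes and numerical tolerances

The test suite and the acceptance script run the Monte-Carlo checks at
the sizes the procedures are specified at: 100 seeds for doublet-flag
recovery, 500 null datasets for its false-flag rate, 50 transfer
iterations for the self-recovery check, 1000 (cell, set) instances for
AUC-oracle agreement, >= 1000 tested combinations for permutation
calibration, 20 seeds for spatial truth recovery, and 200 power / 1000
null cohorts for the survival pipeline. Probability rows are required to
sum to 1 within 1e-8; simplex constructions hold to 1e-12; seeded
re-runs of the transfer agree to 1e-10 (floating-point associativity
aside). The ridge path uses tolerance 1e-4 (CV curve) and 1e-6 (final
fit); hand-oracle comparisons for the elementary statistics are at 1e-10.

## Known limitations

* The t reference for the MAD z is approximate at small n; the
  flagging level is therefore nominal, though measured false-flag rates
  are conservative.
* For two-class problems the underlying binary logistic parameterization
  makes the effective ridge penalty differ by a constant factor from the
  symmetric multinomial parameterization; all shipped procedures use
  >= 3 classes.
* `nnls_deconvolve` assumes linear mixing of mean profiles; systematic
  platform differences between bulk and single-cell measurements are not
  modelled.
* The permutation test shares one shuffle set across pairs; p-values are
  exchangeable but not independent across pairs within a run.
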