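# Methods

This note documents the models and procedures implemented in
`leatsubtype`, the defaults and why they were chosen, the numerical
conventions, and what the synthetic cohorts do and do not emulate.

## Synthetic cohorts

`generate_cohort` simulates a merged multi-dataset bulk-expression cohort
on the log-intensity scale. Expression of gene *g* in sample *j* is

    x_gj = baseline_g + effect · 1[g ∈ markers(subgroup(j))] + γ_b(j),g + ε,
    ε ~ N(0, (δ_b(j),g · noise_sd)²)

with per-gene baselines N(7, 1), additive batch effects γ ~ N(0, 0.5²)
and multiplicative effects δ ~ U(0.8, 1.25) drawn per (batch, gene).
Defaults: 5000 genes, four subgroups of 11/18/13/11 samples, three
batches interleaved across subgroups (so every batch is represented in
every subgroup), 100 disjoint marker genes per subgroup with a 1.5-SD
shift, unit residual SD. Batch effects apply to all genes, markers
included, which is what stresses the correction/clustering interaction in
real merges.

Clinical covariates are drawn per subgroup: recurrence probabilities
(0.09, 0.42, 0.075, 0) and BRAF-V600E probabilities (0, 0.71, 0.08, 0)
make the second subgroup the aggressive, BRAF-driven one; ages center at
(32, 30, 14, 26) years so the third subgroup skews juvenile; histology
mixes follow the subgroup identities (pure DNT; GG/PXA; mostly GG; mixed
DNT/GG). Progression-free survival is exponential with median 36 months
for wild-type samples and a hazard multiplier of 4 for BRAF-mutant ones;
follow-up is censored administratively at the 75th percentile of the
simulated event times, which guarantees both events and censoring without
assuming a follow-up distribution.

Optional **outlier samples** (`n_outliers`) emulate low-tumor-purity
specimens: attenuated, non-specific expression of *all* marker programs
(weight 0.5 × effect) plus inflated noise (SD × 2). They sit near the
center of the subgroup simplex and are the kind of sample that
negative-silhouette filtering is meant to remove.

What the generator does **not** emulate: probe-level microarray artifacts,
correlated gene–gene noise within pathways, gradual purity gradients,
non-exponential survival, or informative censoring. Recovery results on
these cohorts therefore demonstrate correctness of the estimators under
the stated model, not performance guarantees on real data.

## Preprocessing

Datasets are merged on the exact intersection of gene identifiers
(annotation mapping is upstream of this package); sample counts add and
batch labels persist. Batch correction is the parametric empirical-Bayes
location/scale model: per-gene standardisation against the least-squares
grand mean and pooled variance, method-of-moments hyperparameters for a
normal prior on the additive effect and an inverse-gamma prior on the
squared multiplicative effect, and iteration of the coupled posterior-mean
equations to convergence (absolute change < 1e-4, at most 100 iterations).
No reference batch, covariates, or non-parametric priors. Batches need at
least two samples; a single-batch matrix passes through only behind an
explicit flag.

Gene scaling uses the sample (n−1) SD and drops constant rows with a
warning. **Order of operations**: variable-gene selection runs on the
corrected, *unscaled* matrix — after unit-variance scaling every gene has
variance 1 and "most variable" is undefined — and the selected rows are
then scaled, so clustering always sees unit-variance genes.

## Subtype discovery

The sample dissimilarity is 1 − Pearson correlation between profiles over
the selected genes (scale-free after gene scaling and the bulk
transcriptomics convention); Euclidean distance is available. k-medoids
uses the classic PAM BUILD (greedy) + SWAP (best-improvement) heuristic;
because BUILD+SWAP has genuine local optima even on eight points, tiny
instances (≤ 3000 candidate medoid sets) are solved exactly by
enumeration. The algorithm is deterministic given the distance matrix;
all ties (assignment, medoid choice, k selection) break to the smaller
index or smaller k.

The cluster number maximises the mean silhouette width over k = 2..10,
with per-sample widths s(i) = (b − a)/max(a, b) and the s = 0 convention
for singleton clusters. A run whose best mean width stays below 0.05 is
flagged as showing no structure; on null cohorts (no planted effects) the
best width is ≈ 0.006, an order of magnitude below the flag, while the
default cohort peaks near 0.09.

**Core filtering** removes samples with negative silhouette. A structural
note: under nearest-medoid assignment a sample can only get s(i) < 0 when
its medoid ranking disagrees with its mean-dissimilarity ranking. For a
borderline sample with exchangeable affinity to all four subgroups the
assignment is nearly independent of the mean-dissimilarity order, so the
probability of a negative width is bounded by 3/4 and is reached only in
the infinite-noise limit; in practice the filter removes roughly half to
three quarters of planted low-purity outliers while retaining ≥ 90% of
structured samples.

**Consensus clustering** repeats PAM on subsamples (default 80% without
replacement) drawn from a single seeded generator, accumulates
co-clustering frequencies normalised by co-subsampling counts, and
summarises each k by the empirical CDF of the upper-triangle entries at
101 grid points and its trapezoid area. The raw area increases
monotonically with k, so the per-k *change* in area is reported alongside
and the area-based selection should be read as corroboration (stability
of the chosen k), not as an independent selector.

## Signature genes

The nearest-shrunken-centroid classifier standardises each gene's
class-centroid contrast, d_ik = (x̄_ik − x̄_i)/(m_k (s_i + s₀)), with the
pooled within-class SD s_i, offset s₀ = median(s_i), and per-class factor
m_k = √(1/n_k + 1/n) (a fixed convention here; the alternative
√(1/n_k − 1/n) only rescales the threshold grid). Soft-thresholding by Δ
gives d′, shrunken centroids, and the discriminant
δ_k(x) = Σ_i (x_i − x̄′_ik)²/(s_i + s₀)² − 2 log π_k with empirical class
priors.

Δ is chosen on a 30-point grid from 0 to max|d| by stratified
cross-validation (default 5 folds, reduced with a warning when the
smallest class is smaller). Two thresholds attain the minimal CV error:
the *sparsest* (ties to larger Δ) is reported as the classifier — it gives
the most parsimonious signature — while the *most inclusive* (ties to
smaller Δ) feeds the enrichment ranking, because a near-empty score
vector would make the permutation null degenerate. On cleanly separable
synthetic cohorts the error is zero across the whole grid and the two
ends differ substantially; on noisy data they coincide or nearly so.

Per fold, surviving genes are ranked globally by max-class |d′|; ranks
average over the folds in which a gene survived, with sentinel
n_genes + 1 for genes that never survive. Differential expression is the
one-vs-rest Welch t-test per gene with Benjamini–Hochberg adjustment
within each subgroup; zero-variance genes get p = 1 by convention.
Per-sample affiliation likelihoods are the softmax of −δ_k(x)/2.

## Enrichment

Pre-ranked GSEA orders genes by score (ties by identifier), walks the
list adding |score|^p / Σ_hits |score|^p at members (p = 1 by default;
p = 0 recovers the unweighted KS statistic) and subtracting 1/(N − |S|)
at non-members; the ES is the signed extreme deviation, ties reported
positive. A set whose members all carry zero scores falls back to equal
hit weights with a warning; an all-zero ranking is refused. The null
permutes set membership over the gene universe (sample permutation is
undefined for a pre-ranked list). The nominal p is **sign-stratified**:
the observed ES is compared against the same-sign portion of the
permutation null with a pseudocount, which makes null sets reject at the
nominal level (counting against all permutations would double the type-I
rate). NES divides ES by the mean same-sign permutation ES; FDR follows
the sign-stratified NES convention, with plain BH available.

GSVA computes, per gene, a Gaussian-kernel smoothed CDF across samples
(bandwidth = sample SD / 4), ranks genes within each sample by that
density, rescores ranks symmetrically around the list middle, and walks
each set with weights |rank statistic|^τ (τ = 1). The default score is
the difference between the largest positive and largest negative
deviation; the single largest deviation is an option. Scores are
invariant to gene order and to per-gene monotone shifts.

Gene sets use the GMT format with a 5–500 member window after filtering
to the expression universe.

## Clinical statistics

Kaplan–Meier is the product-limit estimator with the median defined as
the smallest time with S(t) ≤ 0.5 (undefined when never reached). The
log-rank test accumulates observed-minus-expected event counts with the
hypergeometric variance over distinct event times (k − 1 df). Cox
regression for a single binary covariate maximises the Breslow partial
likelihood by Newton iteration (steps clipped to ±5, convergence at
1e-9); a monotone likelihood — all events effectively in one group — is
flagged as a non-converged infinite-HR result rather than silently
iterated. Cluster–marker association is the one-vs-rest 2×2 Fisher exact
test per cluster with BH across clusters. Group comparisons use the
unpaired Mann–Whitney rank-sum test (exact for small tie-free samples,
normal approximation with tie correction otherwise) or one-way ANOVA,
with BH across the marker panel; Shapiro–Wilk annotates which is
recommended. The packaged 18-patient clinical table is transcribed
verbatim, including its internal quirks (the printed ages average 26.7
against a narrated 28 ± 14.6, and the recurrence-by-cluster narration
disagrees with the table's cluster column); these are preserved, not
reconciled.

## Pipeline and reproducibility

`run_pipeline` executes the stages in order from one config (YAML or
constructor), writes per-stage TSVs plus a JSON summary, and funnels all
randomness through named per-stage seeds; deterministic stages are
bit-identical across reruns and stochastic stages are identical given the
same seeds. A stage failure aborts with the stage named, keeping earlier
outputs. Default problem sizes throughout (5000 × 53 cohorts, 1000
permutations, 10–50 consensus repetitions, 100-replicate simulations)
keep any single analysis in the seconds-to-minutes range on one core.

## Known limitations

* The ComBat variant is parametric-prior only: no reference batch, no
  covariates, no mean-only mode.
* The Welch one-vs-rest test is not a moderated (empirical-Bayes
  variance) test; with very few samples per group a hierarchical
  variance model would be more powerful.
* BUILD+SWAP PAM is a heuristic above the exact-enumeration size; it can
  return local optima on adversarial instances.
* Negative-silhouette filtering cannot, even in principle, flag more
  than ~3/4 of fully ambiguous samples (see the exchangeability argument
  above); it is a cleanup step, not an outlier detector.
* GSEA p-values are Monte-Carlo estimates; with 1000 permutations the
  smallest attainable nominal p is of order 1e-3.
* The affiliation likelihoods are softmax-calibrated discriminants, not
  posterior probabilities under a generative model; with thousands of
  genes they saturate near 0/1.
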