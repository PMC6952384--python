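# leatsubtype

Transcriptional subtype discovery and outcome statistics for long-term
epilepsy-associated tumors (LEATs: gangliogliomas, dysembryoplastic
neuroepithelial tumors, pleomorphic xanthoastrocytomas).

LEATs are mostly benign tumors causing drug-resistant epilepsy, but a
subset recurs and progresses. Bulk expression profiling of merged cohorts
suggests the histological diagnosis only partially reflects tumor biology:
unsupervised clustering of merged multi-dataset profiles yields four
transcriptional subgroups, one of which — enriched for BRAF-V600E-mutant
gangliogliomas — carries a markedly higher recurrence risk. This package
re-implements that analysis as a tested, reproducible pipeline for anyone
who wants to run or scrutinise it: molecular neuro-oncologists merging
expression cohorts, and methodologists examining how the pieces behave.

## What it computes

* **Batch integration** — gene-space intersection across datasets and the
  parametric empirical-Bayes location/scale adjustment (ComBat): gene-wise
  standardisation, method-of-moments priors (normal on the additive batch
  effect γ, inverse-gamma on the multiplicative δ²), iterative shrinkage
  of per-(batch, gene) estimates, back-transformation.
* **Subtype discovery** — PAM (k-medoids) on the 1000 most variable genes
  with 1 − Pearson sample dissimilarity; the cluster number maximises the
  mean silhouette width s(i) = (b − a)/max(a, b) over k = 2..10; samples
  with s(i) < 0 are excluded as non-core; subsampled consensus clustering
  (co-clustering CDF and its area) corroborates the choice.
* **Signature genes** — nearest-shrunken-centroid classifier
  d_ik = (x̄_ik − x̄_i)/(m_k (s_i + s₀)) with soft-thresholding
  d′ = sign(d)·max(|d| − Δ, 0), Δ chosen by stratified cross-validation;
  genes ranked by |d′| per fold and averaged; one-vs-rest Welch t-tests
  with Benjamini–Hochberg FDR; per-sample subgroup affiliation via the
  softmax of the NSC discriminants.
* **Enrichment** — permutation pre-ranked GSEA (weighted KS running sum,
  sign-stratified permutation p and NES-based FDR) driven by the
  classifier scores, and GSVA (kernel-CDF → symmetric ranks → weighted
  random walk) for set-by-sample scores; GMT I/O.
* **Clinical statistics** — Kaplan–Meier curves, log-rank test,
  single-covariate Cox regression (Newton on the Breslow partial
  likelihood), exact one-vs-rest cluster–marker association, rank-sum /
  ANOVA marker-panel comparisons, Shapiro–Wilk screen.
* **Synthetic cohorts** — a first-class generator planting four subgroups
  (11/18/13/11 samples), 100-gene marker blocks, three batches, and
  outcome-coupled covariates (42% recurrence and 71% BRAF prevalence in
  the aggressive subgroup, PFS hazard ratio 4 for BRAF-mutant samples),
  plus the 18-patient clinical summary table as a packaged fixture.

## Worked example

```python
import leatsubtype as L

expr, clinical, truth = L.generate_cohort(L.CohortConfig(seed=1))
corrected, _ = L.combat_correct(expr)
top = L.scale_genes(L.top_variable_genes(corrected, 1000))
sel = L.select_k_by_silhouette(top, 2, 10)
print(sel.best_k, round(sel.mean_silhouettes[sel.best_k], 3))
```

prints `4 0.086`: the silhouette criterion recovers the four planted
subgroups (peak mean width 0.086 at k = 4 against ≤ 0.06 elsewhere).
Continuing with the classifier and survival stages
(`examples/03_signature_genes.py`, `examples/05_survival.py`) prints

```
CV accuracy: 1.00 (selected Delta = 1.71)
planted markers among the top 400 average ranks: 99.5%
median PFS: wild-type 38.8 vs BRAF-mutant 5.7 months
log-rank chi2 = 35.81 (p = 0.0000); Cox HR = 7.78 [3.62, 16.72]
```

— the cross-validated classifier isolates the planted 400-gene signature
essentially perfectly, and BRAF-mutant samples progress several times
faster (the single-cohort HR estimate scatters around the generator's
true value of 4; the acceptance script's replicate median lands at ~4).

The `examples/` directory holds one short script per capability; the
same stages are scriptable from the shell via the thin `leat-subtype`
CLI (`simulate`, `cluster`, `signatures`, `enrich`, `gsva`, `survival`,
and `run --config pipeline.yaml` for the whole pipeline).

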