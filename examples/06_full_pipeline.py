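"""Run the whole pipeline from one config: simulate -> batch-correct ->
cluster -> signatures -> enrichment -> clinical statistics.

Equivalent to `leat-subtype run --config pipeline.yaml` on the shell.
"""

from leatsubtype import PipelineConfig, run_pipeline

config = PipelineConfig(
    outdir="scratch/example_run",
    simulation={"seed": 1},
    consensus_reps=30,
    gsea_permutations=500,
)
report = run_pipeline(config)
s = report.summary

print(f"selected k = {s['selected_k']} "
      f"(mean silhouette {s['mean_silhouette'][s['selected_k']]:.3f})")
print(f"cluster sizes: {s['cluster_sizes']} -> {s['core_samples']} core samples "
      f"({s['excluded_samples']} excluded)")
print(f"classifier: CV accuracy {s['cv_accuracy']:.2f} at Delta {s['selected_delta']:.2f}")
print(f"enriched sets (q < 0.25) per cluster: "
      f"{ {k: len(v) for k, v in s['enriched_sets'].items()} }")
print(f"clinical: {s['clinical']}")
print(f"full tables written to {config.outdir}/")
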