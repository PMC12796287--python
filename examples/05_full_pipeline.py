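"""Run the whole pipeline (simulate -> features -> ICC -> bootstrap ->
embedding metrics) from a single configuration and list the artifacts.

The same run can be driven from a shell:  sliderep run-all -c config.yaml
"""

from pathlib import Path

import sliderep as sr

config = sr.RunConfig(
    output_dir="scratch/example_run",
    cohort=sr.CohortSpec(n_samples=6, seed=4).scaled(0.15),
    embeddings_spec=sr.EmbeddingSpec(seed=5),
    n_boot=2000,
    per_feature_boot=500,
    n_perm=2000,
)
bundle = sr.run_pipeline(config)

print("artifacts:")
for path in sorted(Path(config.output_dir).iterdir()):
    print("  ", path.name)

print("\nbootstrapped mean ICC per comparison:")
for label, mean in bundle.group_bootstrap.group_means.items():
    print(f"   {label}: {mean:.3f}")
for metric, res in bundle.permutation.items():
    print(f"permutation p ({metric}): {res.p_value:.2e}")
# Every number above is reproducible bit-for-bit from the seeds recorded in
# scratch/example_run/run_record.json.
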