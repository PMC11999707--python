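"""Full planted-signal benchmark: every method scored with insertion and
deletion, aggregated per patch image and per slide, plus Welch p-values."""

from patchexplain.pipeline import RunConfig, run_benchmark

config = RunConfig(
    noise_scale=0.0,
    n_slides=3,
    images_per_slide=2,
    methods=("shapley-exact", "rise-binomial", "rollout", "rollout-res", "ig", "random"),
    seed=1,
)
report = run_benchmark(config)

print(report.summary.to_string(index=False))
print()
print("mean tumor top-k precision per method:")
print(report.precision.groupby("method")["top_k_precision"].mean().to_string())
print()
print("Welch p-values, insertion AUC populations:")
print(report.welch["insertion"].round(4).to_string())
# Removal-based methods (Shapley, RISE) recover every planted tumor patch
# (precision 1.0) and separate sharply from the random baseline; insertion
# is higher and deletion lower for informative rankings.
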