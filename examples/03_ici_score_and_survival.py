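"""Run the full pipeline and test whether the ICI score stratifies survival.

The pipeline deconvolves, clusters, finds DEGs, builds signatures A/B,
computes the per-sample ICI score (PC1A - PC1B), picks the maximally
selected survival cutoff, and compares the high and low score groups.
"""

import numpy as np

from iciscope.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(seed=11, n_samples=150, reps=60, boruta_iter=20)
result = run_pipeline(config, "scratch/example_run")

summary = result.manifest["summary"]
print(f"DEGs: {summary['n_degs']}  "
      f"(signature A: {summary['n_signature_a']}, B: {summary['n_signature_b']})")
print(f"ICI score cutoff: {summary['cutoff']:.3f}")
print(f"log-rank p (high vs low): {summary['logrank_p']:.3g}")
print(f"Spearman(ICI score, true immune fraction): {summary['truth_spearman']:.3f}")
# a Spearman above 0.7 means the score reconstructs the planted immune axis;
# a log-rank p below 0.01 means the score separates survival as designed
hr = result.scores.data.groupby("group")["ici_score"].agg(["size", "mean"])
print(hr.round(3))
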