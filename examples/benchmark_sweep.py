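"""Normalization benchmark: precision/recall/F1/MCC/FPR across DE ratios.

For each assigned DE ratio a paired dataset with known truth is simulated,
each normalizer is applied, DEGs are called at (|log2FC| >= 0.8, p < 0.01),
and the calls are scored against the injected truth set.
"""

from crossnorm import run_benchmark_sweep

table = run_benchmark_sweep(
    de_ratios=[0.2, 0.5],
    methods=["crossnorm_pairwise", "quantile", "baseline"],
    m=3000,
    n=12,
    seed=0,
)
print(table.round(4).to_string(index=False))
print()
print("As the fraction of (mostly up-regulated) DEGs grows, the symmetric-")
print("distribution assumption of quantile and baseline normalization breaks:")
print("their FPR rises and precision falls, while CrossNorm keeps FPR near 0.")
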