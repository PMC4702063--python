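"""Titration trend shapes: monotone mixtures should never yield NMT calls.

Generates a four-mixture titration series (L, M1, M2, K; 24 arrays each)
with a 6:1 skew of upward over downward monotone genes, categorizes every
gene's trajectory into the eight trend classes, and shows the category
histogram before and after CrossNorm. Non-monotonous trends (NMT) are data
artifacts: a mixture series cannot truly rise then fall.
"""

from crossnorm import crossnorm_titration, fixture_titration, quantile_normalize, trend_categorize

matrix, layout, truth = fixture_titration(
    m=2000, replicates=24, upward_fraction=0.3, seed=0
)
print("truth classes:", truth.value_counts().to_dict())

for label, mat in [
    ("raw", matrix),
    ("quantile (all arrays)", quantile_normalize(matrix)),
    ("CrossNorm (adjacent pairs)", crossnorm_titration(matrix, layout)),
]:
    counts = trend_categorize(mat, layout).counts
    print(f"{label:28s} {counts}")
print()
print("The up-categories dominate the down-categories roughly 6:1, mirroring")
print("the truth skew; NMT counts stay near zero for CrossNorm, showing it")
print("does not manufacture non-monotone artifacts.")
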