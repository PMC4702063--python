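"""Why CrossNorm exists: a global expression shift survives it, but not quantile.

Builds a paired dataset whose disease columns sit 1.0 log2 unit above the
controls at every gene (a condition-wide amplification), then compares the
disease-minus-control mean gap before and after each normalization.
"""

import numpy as np

from crossnorm import ExpressionMatrix, StudyDesign, crossnorm_pairwise, quantile_normalize

rng = np.random.default_rng(0)
m, n_pairs = 2000, 10
control = rng.normal(8.0, 1.0, size=(m, n_pairs))
disease = control + 1.0  # every gene up by one log2 unit in disease

matrix = ExpressionMatrix(
    tuple(f"g{i}" for i in range(m)),
    tuple(f"c{j}" for j in range(n_pairs)) + tuple(f"d{j}" for j in range(n_pairs)),
    np.concatenate([control, disease], axis=1),
)
design = StudyDesign.from_pairs([(f"c{j}", f"d{j}") for j in range(n_pairs)])


def gap(mat):
    return mat.values[:, n_pairs:].mean() - mat.values[:, :n_pairs].mean()


print(f"raw disease-control gap:        {gap(matrix):6.3f} log2 units")
print(f"after quantile normalization:   {gap(quantile_normalize(matrix)):6.3f}")
print(f"after pairwise CrossNorm:       {gap(crossnorm_pairwise(matrix, design)):6.3f}")
print()
print("Quantile forces every array onto one distribution, so the genuine")
print("condition-wide shift collapses to ~0; CrossNorm keeps each pair's")
print("difference inside a single cross-column, so the shift survives.")
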