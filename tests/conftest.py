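import numpy as np
import pytest

from crossnorm import ExpressionMatrix, StudyDesign


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 2 samples, the quantile hand example."""
    return ExpressionMatrix(
        ("g1", "g2", "g3"), ("s1", "s2"),
        np.array([[2.0, 8.0], [6.0, 4.0], [4.0, 6.0]]),
    )


@pytest.fixture
def paired_matrix() -> tuple[ExpressionMatrix, StudyDesign]:
    """3 genes, 2 control/disease pairs with a clear upward shift."""
    rng = np.random.default_rng(7)
    values = rng.normal(8.0, 1.0, size=(3, 4))
    values[:, 2:] += 1.0  # disease columns globally shifted up
    matrix = ExpressionMatrix(
        ("g1", "g2", "g3"), ("c1", "c2", "d1", "d2"), values
    )
    design = StudyDesign.from_pairs([("c1", "d1"), ("c2", "d2")])
    return matrix, design


@pytest.fixture
def random_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(11)
    m, n = 50, 6
    return ExpressionMatrix(
        tuple(f"g{i}" for i in range(m)),
        tuple(f"s{j}" for j in range(n)),
        rng.normal(8.0, 1.5, size=(m, n)),
    )
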