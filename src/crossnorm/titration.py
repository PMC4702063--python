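"""Trend-shape analysis for a four-mixture titration series.

A titration experiment hybridises mixtures of two tissues in known
proportions — pure liver (L), 75/25 (M1), 25/75 (M2), pure kidney (K) —
so every transcript's expected expression is monotone across the series
even though no per-gene truth exists. Each gene's trajectory is reduced
to three adjacent-change verdicts (M1-L, M2-M1, K-M2), each significant
up, significant down, or not significant, and the verdict triple is
mapped onto eight trend categories: NST (nothing significant), NMT (at
least one significant increase AND one significant decrease — a data
artifact, since mixtures cannot produce non-monotone truth), and 1/2/3
up or down for monotone trends by their number of significant steps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ExpressionMatrix, StudyDesign
from .normalization import crossnorm_pairwise

__all__ = [
    "MIXTURE_ORDER",
    "TREND_CATEGORIES",
    "TitrationLayout",
    "TrendResult",
    "trend_categorize",
    "fixture_titration",
    "crossnorm_titration",
]

MIXTURE_ORDER = ("L", "M1", "M2", "K")
TREND_CATEGORIES = ("NMT", "NST", "1up", "2up", "3up", "1down", "2down", "3down")


@dataclass(frozen=True)
class TitrationLayout:
    """Arrays of the four mixture groups, in titration order L, M1, M2, K."""

    groups: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if set(self.groups) != set(MIXTURE_ORDER):
            raise ValueError(f"layout needs exactly the groups {MIXTURE_ORDER}")
        sizes = {k: len(v) for k, v in self.groups.items()}
        if min(sizes.values()) < 2:
            raise ValueError(f"every mixture group needs >= 2 arrays: {sizes}")
        if len(set(sizes.values())) != 1:
            raise ValueError(f"replicate counts must be equal: {sizes}")
        object.__setattr__(
            self, "groups", {k: tuple(v) for k, v in self.groups.items()}
        )

    @property
    def replicates(self) -> int:
        return len(self.groups["L"])

    def reversed(self) -> "TitrationLayout":
        """The same arrays traversed in the opposite titration order."""
        return TitrationLayout(
            {
                "L": self.groups["K"],
                "M1": self.groups["M2"],
                "M2": self.groups["M1"],
                "K": self.groups["L"],
            }
        )


class TrendResult(NamedTuple):
    calls: pd.DataFrame  # per gene: step verdicts + category
    counts: dict[str, int]  # category -> gene count (all 8 categories)


def _categorize(verdicts: np.ndarray) -> np.ndarray:
    """Map an (m, 3) array of {+1, -1, 0} step verdicts to categories."""
    ups = (verdicts > 0).sum(axis=1)
    downs = (verdicts < 0).sum(axis=1)
    out = np.empty(verdicts.shape[0], dtype=object)
    out[(ups > 0) & (downs > 0)] = "NMT"
    out[(ups == 0) & (downs == 0)] = "NST"
    for k in (1, 2, 3):
        out[(ups == k) & (downs == 0)] = f"{k}up"
        out[(downs == k) & (ups == 0)] = f"{k}down"
    return out


def trend_categorize(
    matrix: ExpressionMatrix, layout: TitrationLayout, alpha: float = 0.01
) -> TrendResult:
    """Classify every gene's titration trajectory into the 8 categories.

    Each adjacent mixture change (M1-L, M2-M1, K-M2) is tested with a
    two-sample Welch t-test at level ``alpha``; a significant change takes
    the sign of the mean difference.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    blocks = {
        g: matrix.values[:, [matrix.sample_index(s) for s in layout.groups[g]]]
        for g in MIXTURE_ORDER
    }
    m = matrix.n_genes
    verdicts = np.zeros((m, 3), dtype=int)
    frame: dict[str, object] = {}
    for k, (lo, hi) in enumerate(zip(MIXTURE_ORDER[:-1], MIXTURE_ORDER[1:])):
        t, p = stats.ttest_ind(blocks[hi], blocks[lo], axis=1, equal_var=False)
        p = np.where(np.isfinite(p), p, 1.0)
        diff = blocks[hi].mean(axis=1) - blocks[lo].mean(axis=1)
        sig = p < alpha
        verdicts[:, k] = np.where(sig, np.sign(diff).astype(int), 0)
        tag = f"{hi}_minus_{lo}"
        frame[f"diff_{tag}"] = diff
        frame[f"p_{tag}"] = p
        frame[f"verdict_{tag}"] = np.where(
            verdicts[:, k] > 0, "sig_up",
            np.where(verdicts[:, k] < 0, "sig_down", "ns"),
        )
    category = _categorize(verdicts)
    calls = pd.DataFrame(
        {**frame, "category": category},
        index=pd.Index(matrix.gene_ids, name="gene_id"),
    )
    counts = {c: int((category == c).sum()) for c in TREND_CATEGORIES}
    return TrendResult(calls, counts)


def fixture_titration(
    m: int,
    replicates: int,
    upward_fraction: float,
    seed: int,
    downward_fraction: float | None = None,
    nonmono_fraction: float = 0.0,
    step: float = 0.8,
    sigma: float = 0.25,
) -> tuple[ExpressionMatrix, TitrationLayout, pd.Series]:
    """A synthetic titration matrix with known coarse trend classes.

    Genes are monotone-up (fraction ``upward_fraction``, mean rising by
    ``step`` per mixture — the tissue-ratio signal), monotone-down
    (default one sixth of the upward fraction, matching the strong upward
    skew of a kidney-over-liver series), non-monotone (zigzag means, a
    deliberate artifact class) or flat. Returns the matrix, the layout and
    a per-gene truth Series over {up, down, flat, nonmono}.
    """
    if downward_fraction is None:
        downward_fraction = upward_fraction / 6.0
    fractions = upward_fraction + downward_fraction + nonmono_fraction
    if fractions > 1.0:
        raise ValueError("trend-class fractions exceed 1")
    rng = np.random.default_rng(seed)
    n_up = round(m * upward_fraction)
    n_down = round(m * downward_fraction)
    n_non = round(m * nonmono_fraction)

    classes = np.array(["flat"] * m, dtype=object)
    perm = rng.permutation(m)
    classes[perm[:n_up]] = "up"
    classes[perm[n_up:n_up + n_down]] = "down"
    classes[perm[n_up + n_down:n_up + n_down + n_non]] = "nonmono"

    base_mu = rng.uniform(6.0, 10.0, size=m)
    profiles = {
        "up": np.array([0.0, 1.0, 2.0, 3.0]) * step,
        "down": np.array([3.0, 2.0, 1.0, 0.0]) * step,
        "nonmono": np.array([0.0, 1.0, 0.0, 1.0]) * step,
        "flat": np.zeros(4),
    }
    offsets = np.stack([profiles[c] for c in classes])  # (m, 4)

    sample_ids: list[str] = []
    groups: dict[str, tuple[str, ...]] = {}
    columns = []
    for gi, g in enumerate(MIXTURE_ORDER):
        ids = tuple(f"{g}_{r + 1:02d}" for r in range(replicates))
        groups[g] = ids
        sample_ids.extend(ids)
        mean = base_mu + offsets[:, gi]
        columns.append(rng.normal(mean[:, None], sigma, size=(m, replicates)))
    width = len(str(m))
    genes = tuple(f"g{i + 1:0{width}d}" for i in range(m))
    matrix = ExpressionMatrix(genes, tuple(sample_ids), np.concatenate(columns, axis=1))
    truth = pd.Series(classes, index=pd.Index(genes, name="gene_id"), name="truth")
    return matrix, TitrationLayout(groups), truth


def crossnorm_titration(
    matrix: ExpressionMatrix, layout: TitrationLayout, base: str = "quantile"
) -> ExpressionMatrix:
    """CrossNorm applied to a titration series.

    Adjacent mixture groups are cross-normalized pairwise in titration
    order — L with M1 and M2 with K, replicates paired positionally — so
    every array is normalized exactly once and between-mixture shifts
    survive within each cross-column. This pairing is this package's
    convention for titration layouts.
    """

    def _pair_block(lo: str, hi: str) -> ExpressionMatrix:
        ids = list(layout.groups[lo]) + list(layout.groups[hi])
        sub = matrix.subset_samples(ids)
        design = StudyDesign.from_pairs(
            list(zip(layout.groups[lo], layout.groups[hi]))
        )
        return crossnorm_pairwise(sub, design, base)

    block1 = _pair_block("L", "M1")
    block2 = _pair_block("M2", "K")
    out = matrix.values.copy()
    for blk in (block1, block2):
        for sid in blk.sample_ids:
            out[:, matrix.sample_index(sid)] = blk.column(sid)
    return matrix.with_values(out)
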