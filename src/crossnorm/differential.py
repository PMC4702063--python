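"""Differential expression calling and gene-list consistency statistics.

DEG calling follows the MAQC-style dual criterion: a fold-change cutoff
(|log2FC| >= 0.8 by default, log2FC being the disease-minus-control
difference of group means on the log2 scale) combined with a non-stringent
t-test threshold (p < 0.01), with no multiple-testing correction by
default. Consistency between two DEG lists is summarised by the Overlap
Coefficient OC = 2|X∩Y| / (|X| + |Y|) and by the Direction Overlap
Coefficients DOC1/DOC2 (the fraction of each list regulating in the same
direction in the other list's source data).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import ExpressionMatrix, StudyDesign

__all__ = [
    "DEFAULT_FC_THRESHOLD",
    "DEFAULT_P_THRESHOLD",
    "identify_degs",
    "deg_set",
    "direction_map",
    "GeneSetPair",
    "overlap_coefficient",
    "direction_overlap_coefficients",
    "hypergeometric_enrichment",
]

DEFAULT_FC_THRESHOLD = 0.8
DEFAULT_P_THRESHOLD = 0.01


def _patch_undefined(
    t: np.ndarray, p: np.ndarray, diff: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    # zero variance in both groups: t undefined; equal means -> no evidence
    # (t=0, p=1), unequal means with no noise -> certain difference
    bad = ~np.isfinite(t)
    if bad.any():
        zero = diff[bad] == 0.0
        t[bad] = np.where(zero, 0.0, np.where(diff[bad] > 0, np.inf, -np.inf))
        p[bad] = np.where(zero, 1.0, 0.0)
    return t, p


def _welch_t(d: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(d, c, axis=1, equal_var=False)
    diff = d.mean(axis=1) - c.mean(axis=1)
    return _patch_undefined(
        np.asarray(t, dtype=float), np.asarray(p, dtype=float), diff
    )


def _paired_t(d: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_rel(d, c, axis=1)
    diff = (d - c).mean(axis=1)
    return _patch_undefined(
        np.asarray(t, dtype=float), np.asarray(p, dtype=float), diff
    )


def identify_degs(
    matrix: ExpressionMatrix,
    design: StudyDesign,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    paired: bool = False,
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-gene DEG table: log2FC, t, p, direction and the DE flag.

    The default test is the Welch (unequal-variance) two-sample t-test on
    the log2 values; ``paired=True`` switches to the paired t-test over
    the design's pairs. A gene is flagged DE iff |log2FC| >= fc_threshold
    and p < p_threshold; ``fdr=True`` replaces p with its
    Benjamini-Hochberg adjusted value before thresholding (off by
    default).
    """
    controls = design.control_ids
    diseases = design.disease_ids
    if len(controls) < 2 or len(diseases) < 2:
        raise ValueError("DEG calling needs at least 2 samples per group")
    if paired:
        if not design.is_paired:
            raise ValueError("paired t-test requires a paired design")
        controls = [c for c, _ in design.pairs]
        diseases = [d for _, d in design.pairs]
    cidx = [matrix.sample_index(s) for s in controls]
    didx = [matrix.sample_index(s) for s in diseases]
    c = matrix.values[:, cidx]
    d = matrix.values[:, didx]
    log2fc = d.mean(axis=1) - c.mean(axis=1)
    t, p = (_paired_t if paired else _welch_t)(d, c)
    p_eff = multipletests(p, method="fdr_bh")[1] if fdr else p
    is_de = (np.abs(log2fc) >= fc_threshold) & (p_eff < p_threshold)
    direction = np.where(
        is_de & (log2fc > 0), "up", np.where(is_de & (log2fc < 0), "down", "none")
    )
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "t_stat": t,
            "p_value": p_eff,
            "direction": direction,
            "is_de": is_de,
        },
        index=pd.Index(matrix.gene_ids, name="gene_id"),
    )


def deg_set(table: pd.DataFrame) -> set[str]:
    """The gene ids flagged DE in a DEG table."""
    return set(table.index[table["is_de"]])


def direction_map(table: pd.DataFrame, de_only: bool = False) -> dict[str, str]:
    """gene -> up/down by the sign of log2FC (all genes, or DEGs only)."""
    sub = table[table["is_de"]] if de_only else table
    sign = np.where(sub["log2fc"].to_numpy() > 0, "up", "down")
    return dict(zip(sub.index, sign))


@dataclass(frozen=True)
class GeneSetPair:
    """Two DEG sets, optionally with per-gene directions from each source.

    ``x_source_dirs``/``y_source_dirs`` give the regulation direction (sign
    of log2FC) of genes in the *source data* behind each set — they may
    cover more genes than the set itself, so a DEG of X can be checked for
    direction agreement in Y's source even when it is not a DEG of Y.
    """

    x: frozenset[str]
    y: frozenset[str]
    x_source_dirs: Mapping[str, str] = field(default_factory=dict)
    y_source_dirs: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", frozenset(self.x))
        object.__setattr__(self, "y", frozenset(self.y))

    @classmethod
    def from_deg_tables(
        cls, table_x: pd.DataFrame, table_y: pd.DataFrame
    ) -> "GeneSetPair":
        return cls(
            frozenset(deg_set(table_x)),
            frozenset(deg_set(table_y)),
            direction_map(table_x),
            direction_map(table_y),
        )


def overlap_coefficient(x: Iterable[str], y: Iterable[str]) -> float:
    """OC = 2 |X ∩ Y| / (|X| + |Y|); 1.0 when both sets are empty."""
    xs, ys = set(x), set(y)
    if not xs and not ys:
        return 1.0
    return 2.0 * len(xs & ys) / (len(xs) + len(ys))


def direction_overlap_coefficients(pair: GeneSetPair) -> tuple[float, float]:
    """DOC1 and DOC2: per-set fraction of direction-concordant DEGs.

    DOC1 is the fraction of X whose direction matches that gene's
    direction in Y's source data (and symmetrically for DOC2). Genes
    absent from the other source count as discordant; an empty set scores
    1.0 by convention. A gene shared by both sets but missing a direction
    on either side is an error.
    """
    for g in pair.x & pair.y:
        if g not in pair.x_source_dirs or g not in pair.y_source_dirs:
            raise ValueError(f"shared gene {g!r} is missing a direction")

    def one_side(members: frozenset[str], own: Mapping[str, str],
                 other: Mapping[str, str]) -> float:
        if not members:
            return 1.0
        hits = sum(
            1 for g in members if g in other and own.get(g) == other[g]
        )
        return hits / len(members)

    doc1 = one_side(pair.x, pair.x_source_dirs, pair.y_source_dirs)
    doc2 = one_side(pair.y, pair.y_source_dirs, pair.x_source_dirs)
    return doc1, doc2


def hypergeometric_enrichment(
    hits_in_set: int,
    set_size: int,
    hits_in_background: int,
    background_size: int,
) -> float:
    """Upper-tail hypergeometric p-value P(K >= hits_in_set).

    Drawing ``set_size`` genes from a background of ``background_size``
    containing ``hits_in_background`` annotated genes, the probability of
    observing at least the given number of annotated genes in the set.
    """
    if not (0 <= hits_in_set <= set_size <= background_size):
        raise ValueError("inconsistent counts: need 0 <= k <= n <= N")
    if hits_in_set > hits_in_background or hits_in_background > background_size:
        raise ValueError("inconsistent counts: hits exceed the available pool")
    return float(
        stats.hypergeom.sf(
            hits_in_set - 1, background_size, hits_in_background, set_size
        )
    )
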