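"""Normalizers for log2 expression matrices, including the CrossNorm strategy.

Conventional column normalizers (quantile, baseline/median scaling, cyclic
LOESS) force every array toward a common signal distribution, which erases
genuine condition-wide expression shifts — e.g. the global transcriptional
amplification seen in many tumours. CrossNorm avoids this by concatenating
a control column and a disease column into one 2m-length *cross-column*
before normalizing: within a cross-column the between-condition difference
is carried by a single vector, so a rank-preserving column normalizer such
as quantile cannot flatten it. Pairwise CrossNorm builds one cross-column
per matched pair; General CrossNorm builds all n1*n2 control x disease
combinations and averages each sample's normalized copies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .data_model import ExpressionMatrix, StudyDesign

__all__ = [
    "NormalizationMethod",
    "quantile_normalize",
    "baseline_normalize",
    "loess_normalize",
    "crossnorm_pairwise",
    "crossnorm_general",
    "normalize",
    "BASE_NORMALIZERS",
]

_CROSS_METHODS = ("crossnorm_pairwise", "crossnorm_general")
_BASE_METHODS = ("quantile", "baseline", "loess")


@dataclass(frozen=True)
class NormalizationMethod:
    """A named normalizer plus, for CrossNorm variants, its inner base."""

    name: str
    base: str = "quantile"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in _CROSS_METHODS + _BASE_METHODS:
            raise ValueError(f"unknown normalization method {self.name!r}")
        if self.name in _CROSS_METHODS and self.base not in _BASE_METHODS:
            raise ValueError(
                f"CrossNorm base must be one of {_BASE_METHODS}, got {self.base!r}"
            )


# ---------------------------------------------------------------------------
# column normalizers (operate on a plain 2-D array, genes x arrays)
# ---------------------------------------------------------------------------

def _tie_average(sorted_vals: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Reference values by rank, with ties averaged over their rank span."""
    n = sorted_vals.shape[0]
    change = np.empty(n, dtype=bool)
    change[0] = True
    np.not_equal(sorted_vals[1:], sorted_vals[:-1], out=change[1:])
    starts = np.flatnonzero(change)
    sums = np.add.reduceat(ref, starts)
    counts = np.diff(np.append(starts, n))
    return np.repeat(sums / counts, counts)


def _quantile_core(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, axis=0, kind="stable")
    sorted_v = np.take_along_axis(values, order, axis=0)
    ref = sorted_v.mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        out[order[:, j], j] = _tie_average(sorted_v[:, j], ref)
    return out


def _map_to_reference(column: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Quantile-map one column onto a fixed sorted reference distribution."""
    order = np.argsort(column, kind="stable")
    out = np.empty_like(column)
    out[order] = _tie_average(column[order], ref)
    return out


def _baseline_core(values: np.ndarray) -> np.ndarray:
    col_medians = np.median(values, axis=0)
    baseline = np.median(col_medians)
    return values - col_medians + baseline


def _loess_core(
    values: np.ndarray, span: float = 2.0 / 3.0, iterations: int = 1
) -> np.ndarray:
    if values.shape[1] < 2:
        raise ValueError("cyclic LOESS needs at least 2 arrays")
    out = values.copy()
    for _ in range(iterations):
        for a in range(out.shape[1] - 1):
            for b in range(a + 1, out.shape[1]):
                m = out[:, a] - out[:, b]
                if np.ptp(m) < 1e-12:
                    fit = m  # constant offset: the smooth is the offset itself
                else:
                    avg = 0.5 * (out[:, a] + out[:, b])
                    fit = lowess(
                        m, avg, frac=span, it=3, return_sorted=False
                    )
                out[:, a] -= fit / 2.0
                out[:, b] += fit / 2.0
    return out


BASE_NORMALIZERS: dict[str, Callable[..., np.ndarray]] = {
    "quantile": _quantile_core,
    "baseline": _baseline_core,
    "loess": _loess_core,
}


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Classic rank-based quantile normalization.

    The reference distribution is the across-array mean of the sorted
    columns; each value is replaced by the reference value at its
    within-column rank, tied values receiving the mean of the reference
    values over the tied rank span.
    """
    return matrix.with_values(_quantile_core(matrix.values))


def baseline_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Median scaling: shift each array so its median hits the baseline.

    On the log2 scale the scaling is additive; the baseline is the median
    of the per-array medians.
    """
    return matrix.with_values(_baseline_core(matrix.values))


def loess_normalize(
    matrix: ExpressionMatrix, span: float = 2.0 / 3.0, iterations: int = 1
) -> ExpressionMatrix:
    """Cyclic pairwise M-A LOESS normalization.

    For each array pair a locally weighted regression of M = x_a - x_b on
    A = (x_a + x_b)/2 is fitted and half the fitted trend is subtracted
    from one array and added to the other, sweeping all pairs
    ``iterations`` times.
    """
    return matrix.with_values(_loess_core(matrix.values, span, iterations))


# ---------------------------------------------------------------------------
# CrossNorm
# ---------------------------------------------------------------------------

def _resolve_base(base: str | NormalizationMethod, params: dict | None = None):
    if isinstance(base, NormalizationMethod):
        if base.name in _CROSS_METHODS:
            raise ValueError("CrossNorm base must not itself be a CrossNorm variant")
        return BASE_NORMALIZERS[base.name], base.params
    if base not in BASE_NORMALIZERS:
        raise ValueError(f"unknown base normalizer {base!r}")
    return BASE_NORMALIZERS[base], (params or {})


def crossnorm_pairwise(
    matrix: ExpressionMatrix,
    design: StudyDesign,
    base: str | NormalizationMethod = "quantile",
) -> ExpressionMatrix:
    """Pairwise CrossNorm: one cross-column per matched control/disease pair.

    Each pair's two columns are concatenated into a 2m-vector, the n1
    cross-columns are normalized jointly with the base column normalizer,
    and each normalized cross-column is split back into its control (first
    m entries) and disease (last m entries) halves. Sample order of the
    output equals the input.
    """
    if not design.is_paired:
        raise ValueError(
            "crossnorm_pairwise needs a paired design; use crossnorm_general "
            "for unpaired data"
        )
    base_fn, params = _resolve_base(base)
    m = matrix.n_genes
    pairs = design.pairs
    cross = np.empty((2 * m, len(pairs)))
    for k, (c, d) in enumerate(pairs):
        cross[:m, k] = matrix.column(c)
        cross[m:, k] = matrix.column(d)
    normed = base_fn(cross, **params)
    out = np.empty_like(matrix.values)
    for k, (c, d) in enumerate(pairs):
        out[:, matrix.sample_index(c)] = normed[:m, k]
        out[:, matrix.sample_index(d)] = normed[m:, k]
    return matrix.with_values(out)


def crossnorm_general(
    matrix: ExpressionMatrix,
    design: StudyDesign,
    base: str | NormalizationMethod = "quantile",
) -> ExpressionMatrix:
    """General CrossNorm for unpaired designs (pairing, if any, is ignored).

    All n1*n2 cross-columns [C_i; D_j] are normalized jointly; the final
    control profile i is the average of the control halves over the n2
    cross-columns containing C_i, and symmetrically for disease profiles.

    With the quantile base the cross-matrix is never materialized: a first
    pass accumulates the mean sorted distribution, a second pass maps each
    cross-column onto it and accumulates the averages (memory O(m)).
    """
    base_fn, params = _resolve_base(base)
    m = matrix.n_genes
    controls = design.control_ids
    diseases = design.disease_ids
    n1, n2 = len(controls), len(diseases)
    cvals = np.stack([matrix.column(c) for c in controls], axis=1)
    dvals = np.stack([matrix.column(d) for d in diseases], axis=1)

    is_quantile = (
        base == "quantile"
        or (isinstance(base, NormalizationMethod) and base.name == "quantile")
    )
    if is_quantile:
        # pass 1: reference = mean of sorted cross-columns
        ref = np.zeros(2 * m)
        z = np.empty(2 * m)
        for i in range(n1):
            for j in range(n2):
                z[:m] = cvals[:, i]
                z[m:] = dvals[:, j]
                ref += np.sort(z, kind="stable")
        ref /= n1 * n2
        # pass 2: map and average
        c_out = np.zeros((m, n1))
        d_out = np.zeros((m, n2))
        for i in range(n1):
            for j in range(n2):
                z[:m] = cvals[:, i]
                z[m:] = dvals[:, j]
                zn = _map_to_reference(z, ref)
                c_out[:, i] += zn[:m]
                d_out[:, j] += zn[m:]
        c_out /= n2
        d_out /= n1
    else:
        cross = np.empty((2 * m, n1 * n2))
        for i in range(n1):
            for j in range(n2):
                cross[:m, i * n2 + j] = cvals[:, i]
                cross[m:, i * n2 + j] = dvals[:, j]
        normed = base_fn(cross, **params)
        c_out = np.stack(
            [normed[:m, i * n2:(i + 1) * n2].mean(axis=1) for i in range(n1)],
            axis=1,
        )
        d_out = np.stack(
            [normed[m:, j::n2].mean(axis=1) for j in range(n2)], axis=1
        )

    out = np.empty_like(matrix.values)
    for i, c in enumerate(controls):
        out[:, matrix.sample_index(c)] = c_out[:, i]
    for j, d in enumerate(diseases):
        out[:, matrix.sample_index(d)] = d_out[:, j]
    return matrix.with_values(out)


def normalize(
    matrix: ExpressionMatrix,
    method: str | NormalizationMethod,
    design: StudyDesign | None = None,
) -> ExpressionMatrix:
    """Dispatch a normalization by name; CrossNorm variants need a design."""
    if isinstance(method, str):
        method = NormalizationMethod(method)
    if method.name == "quantile":
        return quantile_normalize(matrix)
    if method.name == "baseline":
        return baseline_normalize(matrix)
    if method.name == "loess":
        return loess_normalize(matrix, **method.params)
    if design is None:
        raise ValueError(f"{method.name} requires a study design")
    inner = NormalizationMethod(method.base, params=method.params)
    if method.name == "crossnorm_pairwise":
        return crossnorm_pairwise(matrix, design, inner)
    return crossnorm_general(matrix, design, inner)
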