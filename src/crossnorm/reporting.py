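"""Report writers and the simulate→normalize→call→score benchmark sweep."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .differential import (
    GeneSetPair,
    deg_set,
    direction_overlap_coefficients,
    identify_degs,
    overlap_coefficient,
)
from .evaluation import confusion, metrics
from .normalization import NormalizationMethod, normalize
from .simulation import SimulationConfig, simulate_paired_dataset, synth_base_matrix

__all__ = [
    "format_percentage",
    "percentage",
    "compare_deg_tables",
    "run_benchmark_sweep",
    "write_json",
]


def percentage(numerator: float, denominator: float, decimals: int = 2) -> float:
    """numerator/denominator as a percentage rounded to ``decimals``."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round(100.0 * numerator / denominator, decimals)


def format_percentage(
    numerator: float, denominator: float, decimals: int = 2
) -> str:
    """Render a ratio the way result tables print it, e.g. ``'78.79%'``."""
    return f"{percentage(numerator, denominator, decimals):.{decimals}f}%"


def compare_deg_tables(
    table_a: pd.DataFrame, table_b: pd.DataFrame
) -> dict[str, object]:
    """OC/DOC and common/exclusive counts for two DEG tables.

    The JSON-ready layout of a direction cross-tabulation plus overlap
    report: total and per-direction DEG counts on each side, the common
    and exclusive gene counts, OC, and DOC1/DOC2.
    """
    set_a, set_b = deg_set(table_a), deg_set(table_b)
    pair = GeneSetPair.from_deg_tables(table_a, table_b)
    doc1, doc2 = direction_overlap_coefficients(pair)

    def _by_dir(table: pd.DataFrame) -> dict[str, int]:
        de = table[table["is_de"]]
        return {
            "total": int(len(de)),
            "up": int((de["direction"] == "up").sum()),
            "down": int((de["direction"] == "down").sum()),
        }

    return {
        "a": _by_dir(table_a),
        "b": _by_dir(table_b),
        "common": len(set_a & set_b),
        "exclusive_a": len(set_a - set_b),
        "exclusive_b": len(set_b - set_a),
        "oc": overlap_coefficient(set_a, set_b),
        "doc1": doc1,
        "doc2": doc2,
    }


def run_benchmark_sweep(
    de_ratios: Sequence[float],
    methods: Sequence[str | NormalizationMethod],
    m: int = 2000,
    n: int = 10,
    seed: int = 0,
    fc_threshold: float = 0.8,
    p_threshold: float = 0.01,
    config_overrides: Mapping[str, object] | None = None,
) -> pd.DataFrame:
    """The full simulation benchmark: one row per (de_ratio, method) cell.

    For each DE ratio a paired dataset is simulated once and every method
    is scored on it: normalize, call DEGs at the (fc, p) criteria, and
    cross-tabulate against the injected truth. Columns: de_ratio, method,
    n_degs, precision, recall, f1, mcc, fpr. Deterministic given the seed.
    """
    overrides = dict(config_overrides or {})
    base = synth_base_matrix(m, n, seed)
    rows = []
    for ratio in de_ratios:
        config = SimulationConfig(
            m=m, n=n, de_ratio=ratio, seed=seed + 1, **overrides
        )
        sim = simulate_paired_dataset(base, config)
        truth_set = set(sim.truth.index)
        universe = set(sim.matrix.gene_ids)
        for method in methods:
            name = method if isinstance(method, str) else method.name
            try:
                normed = normalize(sim.matrix, method, sim.design)
                degs = identify_degs(
                    normed, sim.design, fc_threshold, p_threshold
                )
            except Exception as exc:  # tag the failing cell for the caller
                raise RuntimeError(
                    f"benchmark cell (de_ratio={ratio}, method={name}) failed"
                ) from exc
            report = metrics(confusion(deg_set(degs), truth_set, universe))
            rows.append(
                {
                    "de_ratio": ratio,
                    "method": name,
                    "n_degs": len(deg_set(degs)),
                    "precision": report.precision,
                    "recall": report.recall,
                    "f1": report.f1,
                    "mcc": report.mcc,
                    "fpr": report.fpr,
                }
            )
    return pd.DataFrame(rows)


def write_json(payload: Mapping[str, object], path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
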