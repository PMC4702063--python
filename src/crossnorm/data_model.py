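"""Core containers for expression data and study designs.

Expression values are conventionally stored on the log2 intensity scale:
every downstream computation (fold changes as differences of group means,
additive baseline shifts) assumes it. Raw-intensity tables can be
transformed at load time with ``log2_transform``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "StudyDesign",
    "ProbeGeneMap",
    "MatrixLoadError",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_study_design",
    "write_study_design",
    "read_probe_gene_map",
    "collapse_probes_to_genes",
]

CONTROL = "control"
DISEASE = "disease"


class MatrixLoadError(ValueError):
    """Raised when an expression table violates the matrix invariants."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes x samples matrix of log2-scale intensities.

    Invariants: unique gene and sample identifiers, all values finite,
    at least 2 genes and 1 sample.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        genes = tuple(str(g) for g in self.gene_ids)
        samples = tuple(str(s) for s in self.sample_ids)
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape != (len(genes), len(samples)):
            raise MatrixLoadError(
                f"values shape {values.shape} does not match "
                f"{len(genes)} genes x {len(samples)} samples"
            )
        if len(genes) < 2:
            raise MatrixLoadError("an expression matrix needs at least 2 genes")
        if len(samples) < 1:
            raise MatrixLoadError("an expression matrix needs at least 1 sample")
        dup_g = _duplicates(genes)
        if dup_g:
            raise MatrixLoadError(f"duplicate gene ids: {sorted(dup_g)[:5]}")
        dup_s = _duplicates(samples)
        if dup_s:
            raise MatrixLoadError(f"duplicate sample ids: {sorted(dup_s)[:5]}")
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise MatrixLoadError(
                f"non-finite value at gene {genes[bad[0]]!r}, "
                f"sample {samples[bad[1]]!r}"
            )
        object.__setattr__(self, "gene_ids", genes)
        object.__setattr__(self, "sample_ids", samples)
        object.__setattr__(self, "values", values)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def column(self, sample_id: str) -> np.ndarray:
        return self.values[:, self.sample_index(sample_id)]

    def with_values(self, values: np.ndarray) -> "ExpressionMatrix":
        """Same ids, new value block (used by normalizers)."""
        return ExpressionMatrix(self.gene_ids, self.sample_ids, values)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.sample_index(s) for s in sample_ids]
        return ExpressionMatrix(self.gene_ids, tuple(sample_ids), self.values[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            tuple(str(i) for i in frame.index),
            tuple(str(c) for c in frame.columns),
            frame.to_numpy(dtype=float),
        )


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dups: set[str] = set()
    for it in items:
        if it in seen:
            dups.add(it)
        seen.add(it)
    return dups


@dataclass(frozen=True)
class StudyDesign:
    """Sample-to-group assignment with optional control/disease pairing.

    ``assignments`` maps every sample id to ``"control"`` or ``"disease"``;
    ``pairs`` (if given) is a perfect matching of control to disease
    samples, which forces n1 == n2.
    """

    assignments: Mapping[str, str]
    pairs: tuple[tuple[str, str], ...] | None = None

    def __post_init__(self) -> None:
        assignments = dict(self.assignments)
        for sid, grp in assignments.items():
            if grp not in (CONTROL, DISEASE):
                raise ValueError(f"sample {sid!r} has unknown group {grp!r}")
        controls = [s for s, g in assignments.items() if g == CONTROL]
        diseases = [s for s, g in assignments.items() if g == DISEASE]
        if not controls or not diseases:
            raise ValueError("both groups need at least one sample")
        if self.pairs is not None:
            pairs = tuple((str(c), str(d)) for c, d in self.pairs)
            pc = [c for c, _ in pairs]
            pd_ = [d for _, d in pairs]
            if sorted(pc) != sorted(controls) or sorted(pd_) != sorted(diseases):
                raise ValueError(
                    "pairs must form a perfect matching of control and "
                    "disease samples"
                )
            if len(set(pc)) != len(pc) or len(set(pd_)) != len(pd_):
                raise ValueError("a sample appears in more than one pair")
            object.__setattr__(self, "pairs", pairs)
        object.__setattr__(self, "assignments", assignments)

    @property
    def control_ids(self) -> list[str]:
        return [s for s, g in self.assignments.items() if g == CONTROL]

    @property
    def disease_ids(self) -> list[str]:
        return [s for s, g in self.assignments.items() if g == DISEASE]

    @property
    def n1(self) -> int:
        """Number of control arrays."""
        return len(self.control_ids)

    @property
    def n2(self) -> int:
        """Number of disease arrays."""
        return len(self.disease_ids)

    @property
    def is_paired(self) -> bool:
        return self.pairs is not None

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[str, str]]) -> "StudyDesign":
        assignments: dict[str, str] = {}
        for c, d in pairs:
            assignments[c] = CONTROL
            assignments[d] = DISEASE
        return cls(assignments, tuple(pairs))


@dataclass(frozen=True)
class ProbeGeneMap:
    """Many-to-one mapping of probe(-set) ids to official gene symbols."""

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "mapping", {str(p): str(g) for p, g in self.mapping.items()}
        )

    def __getitem__(self, probe_id: str) -> str:
        return self.mapping[probe_id]

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self.mapping


def read_expression_matrix(
    path: str | Path, log2_transform: bool = False
) -> ExpressionMatrix:
    """Load a genes x samples TSV (first column gene ids, header sample ids).

    With ``log2_transform`` raw intensities are mapped v -> log2(v + 1).
    Duplicate ids, missing and non-numeric cells are load errors that name
    the offending row/column.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if frame.index.has_duplicates:
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        raise MatrixLoadError(f"duplicate gene ids in {path}: {dups[:5]}")
    probe = frame.apply(pd.to_numeric, errors="coerce")
    bad = probe.isna()
    if bad.any().any():
        gene = probe.index[bad.any(axis=1)][0]
        col = probe.columns[bad.loc[gene]][0]
        raise MatrixLoadError(
            f"missing or non-numeric value at gene {gene!r}, sample {col!r} in {path}"
        )
    # astype goes through Python's exact string->double conversion;
    # pd.to_numeric's fast path can be off by one ulp
    matrix = ExpressionMatrix.from_frame(frame.astype(float))
    if log2_transform:
        matrix = matrix.with_values(np.log2(matrix.values + 1.0))
    return matrix


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as the package's TSV dialect (header ``gene_id``)."""
    frame = matrix.to_frame()
    frame.index.name = "gene_id"
    # %.17g round-trips IEEE doubles exactly
    frame.to_csv(path, sep="\t", float_format="%.17g")


def read_study_design(path: str | Path) -> StudyDesign:
    """Load a design TSV with columns sample_id, group, pair_id.

    A blank pair_id column means an unpaired design.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample_id", "group"}
    if not required.issubset(frame.columns):
        raise ValueError(f"design table needs columns {sorted(required)}")
    assignments = dict(zip(frame["sample_id"], frame["group"]))
    pairs = None
    if "pair_id" in frame.columns and (frame["pair_id"] != "").any():
        grouped: dict[str, dict[str, str]] = {}
        for _, row in frame.iterrows():
            if row["pair_id"] == "":
                raise ValueError(f"sample {row['sample_id']!r} has no pair_id")
            grouped.setdefault(row["pair_id"], {})[row["group"]] = row["sample_id"]
        pair_list = []
        for pid in sorted(grouped, key=list(grouped).index):
            members = grouped[pid]
            if set(members) != {CONTROL, DISEASE}:
                raise ValueError(
                    f"pair {pid!r} must contain exactly one control and one "
                    f"disease sample"
                )
            pair_list.append((members[CONTROL], members[DISEASE]))
        pairs = tuple(pair_list)
    return StudyDesign(assignments, pairs)


def write_study_design(design: StudyDesign, path: str | Path) -> None:
    rows = []
    pair_of: dict[str, str] = {}
    if design.pairs is not None:
        for k, (c, d) in enumerate(design.pairs, start=1):
            pair_of[c] = pair_of[d] = f"p{k}"
    for sid, grp in design.assignments.items():
        rows.append({"sample_id": sid, "group": grp, "pair_id": pair_of.get(sid, "")})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_probe_gene_map(path: str | Path) -> ProbeGeneMap:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if not {"probe_id", "gene_symbol"}.issubset(frame.columns):
        raise ValueError("probe map needs columns probe_id, gene_symbol")
    if frame["probe_id"].duplicated().any():
        dups = frame.loc[frame["probe_id"].duplicated(), "probe_id"].tolist()
        raise ValueError(f"probe ids mapped more than once: {dups[:5]}")
    return ProbeGeneMap(dict(zip(frame["probe_id"], frame["gene_symbol"])))


def collapse_probes_to_genes(
    matrix: ExpressionMatrix, probe_map: ProbeGeneMap
) -> ExpressionMatrix:
    """Average the rows of all probes mapping to one gene symbol.

    Multiple probe sets for a gene are collapsed to their arithmetic mean
    per sample, on the scale of the stored values. Output genes are sorted
    lexicographically for determinism.
    """
    unmapped = [g for g in matrix.gene_ids if g not in probe_map]
    if unmapped:
        raise KeyError(f"probes without gene mapping: {unmapped[:10]}")
    symbols = pd.Index([probe_map[g] for g in matrix.gene_ids])
    collapsed = matrix.to_frame().groupby(symbols, sort=True).mean()
    return ExpressionMatrix.from_frame(collapsed)
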