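"""Synthetic-data engine: paired tumour/normal simulation and spike-in profiles.

The simulator emulates a two-condition microarray study with a known truth
set. A base matrix of normal-tissue profiles is drawn first (right-skewed
per-gene log2 means on roughly [4, 14], per-gene biological spread), then a
disease group is derived from it: a chosen fraction of genes receives an
assigned log2 fold change (a constant 10% of genes down-regulated, the
remainder up, emulating the unbalanced shifts of cancer transcriptomes),
optionally on top of a condition-wide global shift, with a small centred
chi-squared perturbation of each disease gene mean. The spike-in
constructor mirrors a two-condition spike-in experiment: probes with known
concentration folds > 1 are the true DEGs and the non-DE portion of a
profile is drawn from the unchanged + empty probe pools to hit a requested
DE ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .data_model import ExpressionMatrix, StudyDesign

__all__ = [
    "SimulationConfig",
    "SpikeInDesign",
    "SimulatedDataset",
    "SpikeInProfile",
    "round_half_up",
    "synth_base_matrix",
    "simulate_paired_dataset",
    "fixture_spikein_design",
    "build_spikein_profile",
]


def round_half_up(x: float) -> int:
    """Deterministic rounding used for all truth-set sizes."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the paired disease-vs-normal simulation.

    ``de_ratio`` is the total DEG fraction; ``down_fraction`` of all genes
    (not of DEGs) is down-regulated, so e.g. de_ratio 0.3 means 20% up +
    10% down. Assigned |log2FC| magnitudes are drawn uniformly from
    ``fc_magnitudes``. ``global_shift`` (log2 units) is added to every
    disease gene. The chi-squared mean perturbation is
    noise_scale * (chi2_df - df) / sqrt(2 df): centred, unit-variance,
    scaled to ``noise_scale`` log2 units.
    """

    m: int = 12752
    n: int = 34
    de_ratio: float = 0.3
    down_fraction: float = 0.10
    fc_magnitudes: tuple[float, ...] = (0.8, 1.0, 1.2)
    global_shift: float = 0.0
    noise_scale: float = 0.05
    noise_df: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.de_ratio < 1.0):
            raise ValueError("de_ratio must be in (0, 1)")
        if self.down_fraction > self.de_ratio:
            raise ValueError("down_fraction cannot exceed de_ratio")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be non-negative")


class SimulatedDataset(NamedTuple):
    matrix: ExpressionMatrix
    design: StudyDesign
    truth: pd.DataFrame  # index gene_id; columns direction, assigned_log2fc


class SpikeInProfile(NamedTuple):
    matrix: ExpressionMatrix
    design: StudyDesign
    truth: set[str]


# gene-mean and spread distributions of the synthetic normal-tissue base
_MEAN_OFFSET = 4.0
_MEAN_GAMMA_SHAPE = 2.0
_MEAN_GAMMA_SCALE = 1.5
_MEAN_CLIP = 14.0
_SD_LOW, _SD_HIGH = 0.2, 0.6


def synth_base_matrix(m: int, n: int, seed: int) -> ExpressionMatrix:
    """A synthetic normal-tissue log2 expression matrix (m genes, n arrays).

    Gene means are 4 + Gamma(2, 1.5) clipped at 14 — a right-skewed
    distribution on the usual log2 microarray intensity range — and gene
    spreads are Uniform(0.2, 0.6); sample values are Gaussian around each
    gene's mean. Fully reproducible from the seed.
    """
    if m < 2 or n < 2:
        raise ValueError("need at least 2 genes and 2 samples")
    rng = np.random.default_rng(seed)
    mu = _MEAN_OFFSET + rng.gamma(_MEAN_GAMMA_SHAPE, _MEAN_GAMMA_SCALE, size=m)
    mu = np.minimum(mu, _MEAN_CLIP)
    sigma = rng.uniform(_SD_LOW, _SD_HIGH, size=m)
    values = rng.normal(mu[:, None], sigma[:, None], size=(m, n))
    width = len(str(m))
    genes = tuple(f"g{i + 1:0{width}d}" for i in range(m))
    samples = tuple(f"normal_{j + 1:03d}" for j in range(n))
    return ExpressionMatrix(genes, samples, values)


def simulate_paired_dataset(
    base: ExpressionMatrix, config: SimulationConfig
) -> SimulatedDataset:
    """Derive a paired disease group from a normal base matrix.

    Truth-set sizes are round-half-up of m * de_ratio (total) and
    m * down_fraction (down-regulated); DEGs are picked uniformly at
    random from one shuffled index stream (down first, then up, so the
    down fraction is exact). Each disease gene mean is the normal group
    mean plus the signed assigned log2FC (DEGs only), plus the global
    shift (all genes), plus the centred chi-squared perturbation; disease
    samples are Gaussian around that mean with the gene's base spread.
    Controls are the base columns; pairing is positional.
    """
    if base.n_samples < 2:
        raise ValueError("base matrix needs at least 2 columns")
    m = base.n_genes
    n = base.n_samples
    n_de = round_half_up(m * config.de_ratio)
    n_down = round_half_up(m * config.down_fraction)
    if n_de < 1:
        raise ValueError("de_ratio * m < 1: no DEGs to inject")
    rng = np.random.default_rng(config.seed)

    stream = rng.permutation(m)
    down_idx = stream[:n_down]
    up_idx = stream[n_down:n_de]
    magnitudes = np.array(config.fc_magnitudes, dtype=float)
    assigned = np.zeros(m)
    assigned[down_idx] = -rng.choice(magnitudes, size=n_down)
    assigned[up_idx] = rng.choice(magnitudes, size=n_de - n_down)

    normal_mean = base.values.mean(axis=1)
    gene_sd = base.values.std(axis=1, ddof=1)
    chi2 = rng.chisquare(config.noise_df, size=m)
    noise = config.noise_scale * (chi2 - config.noise_df) / math.sqrt(
        2.0 * config.noise_df
    )
    disease_mean = normal_mean + assigned + config.global_shift + noise
    disease = rng.normal(disease_mean[:, None], gene_sd[:, None], size=(m, n))

    control_ids = [f"control_{j + 1:03d}" for j in range(n)]
    disease_ids = [f"disease_{j + 1:03d}" for j in range(n)]
    values = np.concatenate([base.values, disease], axis=1)
    matrix = ExpressionMatrix(
        base.gene_ids, tuple(control_ids + disease_ids), values
    )
    design = StudyDesign.from_pairs(list(zip(control_ids, disease_ids)))

    de_order = np.concatenate([down_idx, up_idx])
    truth = pd.DataFrame(
        {
            "direction": ["down"] * n_down + ["up"] * (n_de - n_down),
            "assigned_log2fc": assigned[de_order],
        },
        index=pd.Index([base.gene_ids[i] for i in de_order], name="gene_id"),
    ).sort_index()
    return SimulatedDataset(matrix, design, truth)


@dataclass(frozen=True)
class SpikeInDesign:
    """Per-probe spike-in annotation: category and known concentration fold.

    Categories partition the probe set into ``assigned_fc`` (fold > 1, the
    true DEGs), ``unchanged`` (fold == 1) and ``empty`` (nothing spiked).
    """

    table: pd.DataFrame  # index probe_id; columns category, fold

    def __post_init__(self) -> None:
        cats = set(self.table["category"].unique())
        if not cats <= {"assigned_fc", "unchanged", "empty"}:
            raise ValueError(f"unknown spike-in categories: {cats}")
        fc = self.table[self.table["category"] == "assigned_fc"]
        if (fc["fold"] <= 1).any():
            raise ValueError("assigned_fc probes must have fold > 1")

    def probes(self, category: str) -> list[str]:
        return list(self.table.index[self.table["category"] == category])

    @property
    def counts(self) -> dict[str, int]:
        return self.table["category"].value_counts().to_dict()


# composition mirroring a classic two-condition spike-in chip: 14,010 probe
# sets, 1,331 with fold > 1, 2,535 spiked at unchanged concentration
_SPIKE_TOTAL = 14010
_SPIKE_FC = 1331
_SPIKE_UNCHANGED = 2535
_SPIKE_FOLDS = (1.2, 1.5, 1.7, 2.0, 2.5, 3.0, 3.5, 4.0)


def fixture_spikein_design(
    seed: int,
    n_probes: int = _SPIKE_TOTAL,
    n_assigned_fc: int = _SPIKE_FC,
    n_unchanged: int = _SPIKE_UNCHANGED,
) -> SpikeInDesign:
    """A synthetic spike-in annotation with the canonical category counts.

    Deterministic from the seed: which probes carry which fold varies with
    the seed, the three category counts never do. Folds are drawn from a
    small discrete set of concentration ratios >= 1.2.
    """
    if n_assigned_fc + n_unchanged > n_probes:
        raise ValueError("category counts exceed the probe total")
    rng = np.random.default_rng(seed)
    width = len(str(n_probes))
    probes = [f"probe_{i + 1:0{width}d}" for i in range(n_probes)]
    perm = rng.permutation(n_probes)
    category = np.full(n_probes, "empty", dtype=object)
    category[perm[:n_assigned_fc]] = "assigned_fc"
    category[perm[n_assigned_fc:n_assigned_fc + n_unchanged]] = "unchanged"
    fold = np.ones(n_probes)
    fold[perm[:n_assigned_fc]] = rng.choice(_SPIKE_FOLDS, size=n_assigned_fc)
    fold[category == "empty"] = np.nan
    table = pd.DataFrame(
        {"category": category, "fold": fold},
        index=pd.Index(probes, name="probe_id"),
    )
    return SpikeInDesign(table)


def build_spikein_profile(
    design: SpikeInDesign,
    de_ratio: float,
    replicates_per_group: int = 3,
    seed: int = 0,
    array_noise_sd: float = 0.25,
) -> SpikeInProfile:
    """Assemble a two-condition expression profile from a spike-in design.

    All ``assigned_fc`` probes enter as true DEGs; the profile is padded
    with non-DE probes sampled without replacement from the unchanged +
    empty pools until the DE fraction equals ``de_ratio`` (total size =
    round(|DE| / de_ratio)). Each condition gets ``replicates_per_group``
    arrays; the disease arrays are elevated by log2(fold) on the DE probes
    and carry Gaussian array noise.
    """
    if not (0.0 < de_ratio <= 1.0):
        raise ValueError("de_ratio must be in (0, 1]")
    rng = np.random.default_rng(seed)
    de_probes = design.probes("assigned_fc")
    n_de = len(de_probes)
    total = round_half_up(n_de / de_ratio)
    n_non = total - n_de
    pool = design.probes("unchanged") + design.probes("empty")
    if n_non > len(pool):
        raise ValueError(
            f"need {n_non} non-DE probes but the unchanged+empty pool has "
            f"only {len(pool)}"
        )
    non_de = [pool[i] for i in rng.choice(len(pool), size=n_non, replace=False)]
    probes = de_probes + non_de

    mu = _MEAN_OFFSET + rng.gamma(
        _MEAN_GAMMA_SHAPE, _MEAN_GAMMA_SCALE, size=total
    )
    mu = np.minimum(mu, _MEAN_CLIP)
    shift = np.zeros(total)
    folds = design.table.loc[de_probes, "fold"].to_numpy(dtype=float)
    shift[:n_de] = np.log2(folds)

    r = replicates_per_group
    control = rng.normal(mu[:, None], array_noise_sd, size=(total, r))
    disease = rng.normal(
        (mu + shift)[:, None], array_noise_sd, size=(total, r)
    )
    control_ids = [f"control_{j + 1}" for j in range(r)]
    disease_ids = [f"disease_{j + 1}" for j in range(r)]
    matrix = ExpressionMatrix(
        tuple(probes),
        tuple(control_ids + disease_ids),
        np.concatenate([control, disease], axis=1),
    )
    study = StudyDesign.from_pairs(list(zip(control_ids, disease_ids)))
    return SpikeInProfile(matrix, study, set(de_probes))
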