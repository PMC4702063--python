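# Methods

## Model and procedure

All computation is on the log2 intensity scale, so a fold change is a
difference of group means and additive shifts model multiplicative signal
changes. Inputs are assumed background-corrected; background correction
and probe summarization are out of scope, though `collapse_probes_to_genes`
averages multiple probe rows per gene symbol (on the stored scale — if the
log2 load flag was used, averaging happens after the transform) and orders
output genes lexicographically for determinism.

**Quantile normalization.** The reference distribution is the across-array
mean of the within-array sorted values; each value is replaced by the
reference value at its within-array rank. Tied values receive the mean of
the reference values over the tied rank span — deterministic, and the same
convention for every code path. Ranks come from a stable sort, so equal
values keep input order before tie-averaging.

**Baseline (median scaling).** Each array is shifted additively so its
median equals the median of all array medians. **Cyclic LOESS.** For each
unordered array pair, M = x_a − x_b is smoothed against A = (x_a + x_b)/2
(statsmodels lowess, span 2/3, 3 robustness iterations) and half the fit is
subtracted from a / added to b; corrections are applied immediately and the
sweep runs once by default (both configurable). When M is constant to
machine precision the smooth is taken to be that constant exactly, so a
pure offset pair is recentred without smoother noise.

**Pairwise CrossNorm.** One cross-column Zᵢ = [Cᵢ; Dᵢ] per matched pair;
the n₁ cross-columns are normalized jointly with the base normalizer
(quantile unless configured otherwise) and split back. Key consequence:
the normalization applied within a cross-column is monotone, so the sign
of every within-pair difference is preserved — the mechanism behind the
direction-fidelity results. Output sample order always equals input order,
and the result is invariant to the order in which pairs are listed.

**General CrossNorm.** All n₁·n₂ cross-columns [Cᵢ; D_j]; after joint
normalization, each control profile is the average of its n₂ normalized
control halves and each disease profile the average of its n₁ disease
halves. With the quantile base this is computed in two streaming passes —
pass 1 accumulates the summed sorted cross-columns into the reference,
pass 2 maps each cross-column onto the reference and accumulates the
averages — so memory stays O(m) rather than O(m·n₁n₂). Non-quantile bases
materialize the cross-matrix. With n₁ = n₂ = 1 the two variants coincide
exactly.

**DEG calling.** Welch (unequal-variance) two-sample t-test per gene; the
calling rule is |log2FC| ≥ 0.8 (inclusive) AND p < 0.01 (exclusive), with
no multiple-testing correction by default — the MAQC-style recipe of a
fold-change ranking guarded by a non-stringent p threshold. A paired-t
option and an optional Benjamini–Hochberg adjustment exist but are off by
default. Degenerate genes (zero variance in both groups): equal means give
t = 0, p = 1; unequal means give ±∞, p = 0.

**Consistency.** OC uses the Dice form 2|X∩Y|/(|X|+|Y|): it is the unique
common overlap variant that reproduces the published consistency
percentages from their printed counts (2·2074/(2087+2097) = 99.14%,
2·3111/(3120+3145) = 99.31%); min- and max-denominator variants do not.
DOC1 is the fraction of set X whose regulation direction matches that
gene's direction in the other list's source data; genes absent from the
other source count as discordant. Empty-set conventions (OC of two empty
sets = 1, DOC of an empty set = 1) are vacuous-truth choices, documented
because the formulas are 0/0 there.

**Metrics.** Standard 2×2 formulas; any metric with a zero denominator
returns 0 with a logged warning (for MCC, 0 is the random-prediction
value, making the convention continuous with its interpretation). ROC
curves are deliberately omitted: DEG calling uses one fixed cutoff, so a
cutoff-sweeping summary answers a different question than MCC/F1 at the
operating point.

**Titration trends.** Adjacent-mixture changes (M1−L, M2−M1, K−M2) are
tested with per-pair Welch t-tests at α = 0.01 (configurable); a gene's
verdict triple maps onto eight categories — NMT if at least one
significant increase and one significant decrease coexist (a physical
impossibility for true mixture signals, hence an artifact detector), NST
if nothing is significant, otherwise k·up/k·down by the count of
significant one-directional steps. The dedicated monotone trend test of
the original titration-QA tooling is not reproduced; the per-pair Welch
scheme preserves the category logic, which is what the package's claims
rest on. For CrossNorm on a titration layout, adjacent groups are
cross-normalized pairwise in titration order (L↔M1 and M2↔K, replicates
paired positionally) so each array is normalized exactly once; this
pairing is this package's convention for four-group layouts.

## Synthetic data

`synth_base_matrix` draws gene means from 4 + Gamma(shape 2, scale 1.5)
clipped at 14 — a right-skewed distribution spanning the usual log2
microarray intensity range — and gene-level spreads from Uniform(0.2, 0.6);
arrays are Gaussian per gene. The default study scale is 12,752 genes and
34 arrays per group, the size of the normal-esophagus template the
simulation design emulates.

`simulate_paired_dataset` injects round(m·de_ratio) DEGs, of which
round(m·down_fraction) are down-regulated (default 0.10 of *all* genes,
constant across DE ratios, so a 30% DE ratio means 20% up + 10% down).
Assigned magnitudes are drawn uniformly from {0.8, 1.0, 1.2} log2 units —
note the smallest magnitude sits exactly on the calling threshold, which
caps recall near 0.8 by construction. Each disease gene mean is the normal
group mean + signed magnitude + optional global shift + a centred
chi-squared perturbation noise_scale·(χ²_df − df)/√(2df) with df = 4 and
noise_scale = 0.05 log2 units (small against the biological spread; both
configurable, as no canonical values exist for this term). Disease arrays
are Gaussian around that mean with the gene's base-sample spread; controls
are the base columns; pairing is positional. Rounding is half-up
throughout so truth sizes are exactly reproducible. Down-DEGs are taken
first from one shuffled index stream, then up-DEGs, so the down count is
exact.

The spike-in fixture mirrors a classic two-condition spike-in chip:
14,010 probes, 1,331 with concentration fold > 1 (the truth set; folds
from a discrete grid 1.2–4.0), 2,535 at unchanged concentration, the rest
empty. `build_spikein_profile` includes every fold>1 probe and pads with
round(|DE|/de_ratio) − |DE| non-DE probes sampled from the unchanged+empty
pool (e.g. 4,437 probes at DE ratio 0.3), with 3 replicate arrays per
condition by default. An alternative construction — sweeping the fold
threshold rather than the non-DE pool — is noted but not implemented,
because the pool construction reproduces the published profile sizes.

The titration fixture builds monotone-up, monotone-down (default one sixth
of the up fraction, matching the strong upward skew of a
kidney-over-liver series), flat and optional zigzag genes with step 0.8
log2 units per mixture and within-group spread 0.25.

**What the generators do not emulate:** probe-level effects
(cross-hybridization, PM/MM), spatial artifacts, batch structure,
heavy-tailed and intensity-dependent noise, correlated genes. Passing
tests therefore demonstrate the algorithmic properties of the normalizers
and callers under the stated generative model, not end-to-end performance
on raw array data.

## Numerical choices

- Quantile tie handling and stable ranks as above; idempotence holds to
  ~1e-12.
- Streaming General CrossNorm accumulates sums in float64; its agreement
  with the literal materialized recipe is asserted at 1e-12 in tests.
- Welch p-values from scipy; undefined cases patched per the degenerate
  rules above rather than propagating NaN.
- Matrix TSV I/O writes `%.17g`, which round-trips IEEE doubles exactly;
  the reader parses through exact string→double conversion.
- `metrics` and OC/DOC zero-denominator conventions are warnings, never
  exceptions.

## Problem sizes used by the shipped checks

The end-to-end checks run the full pipeline at the study scale (12,752
genes × 34 pairs, DE ratios 0.2–0.5, five seeds for the FPR bound, one
seed for the Pairwise-vs-General comparison); unit and property tests use
hundreds to a few thousand genes, which is ample for the invariants they
assert.

## Known limitations

- General CrossNorm assumes all cross-columns share a distribution; with
  very heterogeneous arrays the averaging step shrinks per-sample
  character.
- CrossNorm corrects technical variation that is independent of condition;
  it is not a batch-effect remover, and confounded batches remain
  confounded after it.
- The LOESS normalizer is a pragmatic cyclic implementation; none of the
  package's quantitative claims depend on its specifics.
- The trend categorizer's per-pair t-tests ignore the ordering information
  a dedicated isotonic trend test would exploit; category counts at a
  given α are therefore conservative for weak monotone genes.
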