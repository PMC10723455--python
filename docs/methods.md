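# Methods

This note documents the statistical models implemented in `sccycle`,
the defaults and why they were chosen, the numerical conventions, and
the known limitations — in particular what the synthetic-data generator
does and does not emulate about real single-cell data.

## Data model

The universal container is a genes × cells matrix of finite,
non-negative normalized expression values with per-cell metadata
(collection time in hours, cluster label, condition label). Values are
consumed as-is: normalization, QC, and clustering are upstream concerns
and the toolkit performs none of them. Timepoints are stored as
absolute hours (not folded into the period) so multi-day designs work;
each detector folds times into its period itself, rounding fold-times
to 9 decimals before grouping so that floating-point noise cannot split
a timepoint.

On disk, the MatrixMarket dialect stores the matrix cells × genes (the
common single-cell export convention) with gene and cell id sidecars
(`<matrix>.genes.tsv`, `<matrix>.cells.tsv`); it is transposed to
genes × cells on load. The CSV dialect stores genes × rows directly.
CSV parsing uses round-trip float precision, so `load ∘ write` is the
identity for both dialects.

## Harmonic regression (cosinor)

For observations `(y_i, t_i)` and period τ (default 24 h,
ω = 2π/τ), ordinary least squares fits

    y = M + β₁ cos(ωt) + β₂ sin(ωt) + ε .

Amplitude is `A = √(β₁² + β₂²)`, phase is the fitted peak time
`φ = atan2(β₂, β₁)/ω` mapped into `[0, τ)`, and the p-value comes from
the F-test of `(β₁, β₂) = (0, 0)` with `(2, n − 3)` degrees of
freedom. The design requires at least 4 observations covering at least
3 distinct fold-times (otherwise the design matrix is rank deficient).
Degenerate cases: a constant series reports `F = 0, p = 1, A = 0`; an
exact fit with nonzero amplitude (zero residual variance) reports the
smallest positive double as p with a `degenerate_fit` flag rather than
a division by zero. p-values are invariant to positive affine
transforms of `y`.

## Jonckheere–Terpstra machinery

For ordered groups `g_1, …, g_k` the trend statistic is

    JT = Σ_{i<j} #{(a ∈ g_i, b ∈ g_j) : y_b > y_a}   (ties count ½).

Three nulls are available:

- **Exact** (tie-free, `N ≤ 50` by default): pooling groups left to
  right, the increment from merging the next group into the pooled
  block is an independent Mann–Whitney statistic, so the JT null pmf is
  the convolution of Mann–Whitney pmfs, each computed by the
  Gaussian-binomial recurrence
  `[M,k]_q = [M−1,k−1]_q + q^k [M−1,k]_q`. The pmf is validated in the
  test suite against exhaustive permutation enumeration for every
  group-size vector with `N ≤ 8`.
- **Tie-corrected normal approximation** (the default whenever ties are
  present or `N > 50`): mean `(N² − Σn_i²)/4` and the standard
  tie-corrected variance built from group sizes and pooled tie-group
  sizes, with a 0.5 continuity correction toward the mean. On tie-free
  data at `N ≥ 40` its p-values agree with the exact pmf to within
  0.01.
- **Seeded Monte-Carlo permutation null** on request (default 10⁵
  permutations). It is not the default for tied data because per-gene
  permutation nulls are prohibitively slow for ensemble-scale runs
  (10⁵ permutations × thousands of genes); the normal approximation's
  calibration under heavy ties is checked directly by the type-I
  acceptance test over the full simulation grid.

Two-sided p-values double the smaller tail and cap at 1 (the tie-free
null is symmetric about its mean).

## JTK-style template test

Templates are cosines of the detector's period discretized at the
distinct fold-times, one per phase in the phase grid (default: one
phase per fold-time), optionally with asymmetric rise/fall warping
(default: symmetric only — template multiplicity costs power, so the
default grid is minimal). Each template induces a rank ordering of the
timepoint groups; groups with tied template values are merged (pairs
between them carry no signal either way). Identical orderings arising
from different phases are deduplicated. Per template, the two-sided JT
p-value is computed against the appropriate null; the reported p-value
is the minimum times the number of distinct templates (Bonferroni),
capped at 1, and the reported phase is the arg-min template's phase.

## RAIN-style umbrella test

For peak position `m` the umbrella statistic is the JT statistic of the
rising segment (groups `1..m`) plus that of the reversed falling
segment (groups `k..m`); the peak group belongs to both. The test is
one-sided (large statistics indicate the umbrella shape). Candidate
shapes are all `k` peak positions plus the `k − 2` interior trough
positions (inverted umbrellas, evaluated on `−y`; troughs at the ends
duplicate the monotone peak shapes at the opposite ends and are
skipped), giving `2k − 2` shapes under a Bonferroni correction. A
boundary peak reduces to a monotone trend test and is flagged. The
reported phase is the best peak's fold-time; for a winning trough
shape, the endpoint with the larger observed mean.

The null of the combined statistic: in exact mode (tie-free, small N)
it is the convolution of the two segment nulls, i.e. the two segments
are treated as independent. That construction is measurably liberal at
scale — the segments share the peak timepoint's cells, and under the
permutation null each shared cell contributes a covariance of 1/12 per
(before-cell, after-cell) pair, i.e.
`Cov ≈ n_peak · N_before · N_after / 12` (verified by simulation).
The normal-approximation path therefore uses
`Var = Var_rise + Var_fall + 2·Cov` with the tie-free covariance (ties
only shrink it, so this errs conservative). Without the term the
empirical type-I error on flat negative-binomial data at `N = 60` is
≈ 0.057 at α = 0.05; with it ≈ 0.03.

All observations are treated as cross-sectional (independent cells);
there is no longitudinal mode.

## Multiple testing

Benjamini–Hochberg step-up q-values
(`q_(i) = min_{j≥i} p_(j)·m/j`, capped at 1), computed via
statsmodels and cross-checked in the tests against a literal
transcription of the rule. Following the reliability analyses, the
*unadjusted* p < 0.05 threshold is the default for concordance and
overlap detection (FDR-thresholding reduces subsample concordance);
adjusted mode is available behind a flag.

## Pseudo-bulk

The pseudo-bulk value of gene g at time t is the arithmetic mean of the
cluster's cells at t (not a summed raw-count pseudobulk, which is a
different convention and out of scope). No minimum-cell filter is
imposed here; callers wanting "at least two cells at each timepoint"
apply it via `subset`.

## Subsample concordance and overlap detection

`split_half` halves the cells independently within each timepoint
(both halves therefore cover every timepoint); with an odd count the
extra cell goes to sub-experiment 1 — any fixed convention works, this
one is fixed for determinism. Per-trial seeds derive from the master
seed through `numpy.random.SeedSequence.spawn`, so individual trials
are reproducible. A concordance run reports `N_full` (cyclers detected
with all cells), per-trial `(N₁, N₂, N_∩)`, and the mean ± sd of
`N_∩ / N_full` over trials (default 10). `N_full` is the denominator
because the union of half-detections is typically far smaller than
`N_full`; the Jaccard ratio is reported alongside for completeness.
`N_full = 0` yields a null ratio with a flag, never a zero.

The overlap detector returns genes with harmonic p < α in both halves
of one seeded split (with `n_splits > 1`, a strict-majority extension,
flagged in the output). If the two halves were independent its
false-positive rate would be α²; in practice the halves share the
timepoint structure, so the suite asserts the implied inequality
(overlap FPR ≤ single-run FPR) rather than exact independence.

## Contamination model

`X̃(c, t*) = X(c, t*) + λ·⟨X⟩`, where `⟨X⟩` is the gene's mean over
all of the cluster's cells at all timepoints, computed on the
*pristine* data — also inside sweeps, so λ grid cells are independent
and contamination is never compounded (contaminating twice is not
additive, because the second grand mean would include the first
elevation). Candidate genes for contamination studies follow the
selection rule: detectably expressed in ≥ 50% of the cluster's cells
and cells-as-replicates harmonic p > 0.9. The default λ grid is 0–5 in
steps of 0.25: identity at one end, beyond rank saturation on the test
fixtures at the other.

## Synthetic ensemble

Counts are `NB(μ(t), r)` in the size parameterization
`Var = μ + μ²/r` (numpy's `negative_binomial(n=r, p=r/(r+μ))`). Note
the convention: larger `r` (here called dispersion, matching common
usage for the size parameter) means *less* noise. Means are
`μ(t) = template(t) + μ0` with templates affinely normalized to span
[0, 100]; constant templates are rejected as degenerate.

Default ensemble design: 20 cycling + 20 non-cycling templates × 5
baseline offsets `μ0 ∈ {0.1, 1, 10, 100, 500}` × 7 dispersions
log-spaced on `[0.001, 5]` (log spacing matches the scales on which
real single-cell dispersion estimates vary), sampled at 12 timepoints
2 h apart (one full 24-h cycle) with 5 replicates each — 1400 labeled
series, reshaped into a 1400-gene × 60-cell dataset with a single
synthetic cluster. Per-series seeds derive from the master seed.

Templates can be extracted from a supplied real dataset (the 20 genes
with the lowest harmonic p-values, and 20 genes passing the non-cycler
rule); the no-download default is parametric: cycling templates are
normalized cosines at an even phase grid (optionally sharpened), and
non-cycling templates are seeded jitter with the fundamental circadian
harmonic projected out before normalization, so they carry exactly no
24-h component while still spanning [0, 100] like the cycling shapes.

What the generator does *not* emulate: cell-to-cell correlation within
a collection (each cell is an independent NB draw), explicit
dropout/zero-inflation beyond what low-`r` NB produces, library-size
variation, per-gene cell-type structure, or uneven cells per timepoint
in the default design (the loader and detectors support unevenness; the
generator keeps the balanced design that all compared methods can
handle). Consequently, passing type-I/power tests on this generator
demonstrates calibration and power against independent overdispersed
count noise — not robustness to correlated artifacts, which is probed
separately and deliberately by the contamination model.

## Evaluation

ROC curves sweep p-value thresholds ascending (ties share a
threshold); the trapezoid AUC equals the Mann–Whitney rank AUC with
ties counted ½, and is checked against an O(n²) pairwise oracle.
Reference cycler lists are consumed as one-gene-per-line text, matched
by exact id with an optional case-folding flag; reference genes absent
from the scored results are dropped with a logged count. Grid
performance recomputes TPR/FPR per (μ0, dispersion) cell directly from
the results and truth tables, with a coverage error if any series is
missing.

Runtime trend classification fits `t = a·m + b`, `t = a·m² + b`, and
`log t = a·m + b`. Timing noise is multiplicative, so the polynomial
models are fit by least squares on the relative scale (weights `1/t`)
and all three are compared by relative RMS error; absolute-scale fits
can drive the intercept negative at small sizes and misclassify planted
curves. Wall-clock benchmarking is a harness only — timings are never
asserted.

## Problem sizes used by the test and acceptance runs

Type-I calibration uses 1000 flat-NB series per (μ0, r) grid cell for
each of the three detectors; the ensemble-structure checks use three
independent 1400-series default ensembles; the overlap-FPR comparison
uses 50 null replicates of 150 genes; NB moment checks use 2×10⁴ draws
per grid cell with self-calibrated (fourth-moment) Monte-Carlo error
bars. The contamination analysis uses a 600-gene, 40-cells-per-timepoint
fixture whose non-cycler panel (≈ 69 genes) is chosen by the selection
rule above. These sizes are the package's chosen study conditions and
are fixed in the test suite.

## Known limitations

- Only one period is tested per run (no period scanning, no
  multi-component cosinor).
- The Bonferroni correction across templates/shapes is a deliberately
  simple, conservative convention; the original JTK/RAIN adjustments
  differ in detail.
- Exact JT nulls require tie-free data; count data essentially always
  ties, so ensemble-scale runs rely on the tie-corrected normal
  approximation (calibration verified empirically, slightly
  conservative).
- The umbrella exact mode keeps the independence convolution of segment
  nulls; only the normal path carries the covariance correction.
- No ARSER/SW1PerS/TimeCycle, no loom/HDF5 I/O, no plotting (outputs
  are TSV/JSON for any plotting layer).
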