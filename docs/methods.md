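# Methods

## Model and statistic

For one column triple (x, y, z) the model is the two-covariate linear
regression with interaction,

    y = β₀ + β₁·x + β₂·z + β₃·x·z + ε,   ε ~ i.i.d. N(0, σ²),

and the quantity of interest is the two-sided t-test of H₀: β₃ = 0. By the
Frisch–Waugh–Lovell theorem, the OLS estimate of β₃ and its t statistic are
unchanged if both y and the interaction product x·z are residualized
against the remaining design columns {1, x, z}. The t statistic is then a
function of the partial correlation r between y and x·z given {1, x, z}:

    t = r·√(DF / (1 − r²)),   DF = n − 4,

with n − 4 residual degrees of freedom because the full design has four
columns (intercept and three slopes). This identity is exact, so the screen
and a full OLS fit are the same test; the test suite verifies agreement to
a relative error of 1e-10 over hundreds of random triples, and the refit
module is the brute-force oracle.

## Blocked computation

A naive triple loop would redo the design orthogonalization p₂ times per
(x, z) pair. The screen instead:

1. centers every column of X, Y, Z once, caching each column's mean and
   centered sum of squares;
2. per (x, z) pair, builds an orthonormal basis by Gram–Schmidt —
   q₂ ∝ centered x, q₃ ∝ z residualized on q₂, q₄ ∝ centered x·z
   residualized on {q₂, q₃}. The product x·z is formed from the *raw*
   (uncentered) columns, then centered: the interaction of centered
   variables spans a different model and would not reproduce the full fit;
3. per outcome column y, computes r = ⟨y, q₄⟩ / √(ssy − ⟨y, q₂⟩² − ⟨y, q₃⟩²)
   from three inner products — ⟨y, q₂⟩ is hoisted out of the inner loop, so
   the per-(pair, outcome) work is two length-n dot products.

The outer loop runs over whichever of X/Z has more columns (the partial
correlation is symmetric in x and z, so this reorders computation without
changing results) and is partitioned across workers in contiguous blocks.
Thread workers are used because the compiled kernels release the GIL.

## Bit-level determinism

Chunked multi-file runs are required to equal whole-matrix runs *exactly*,
and any worker count must give identical output. Vectorized BLAS/numpy
reductions cannot deliver this: their accumulation order (and hence the
last-ulp rounding) depends on matrix shape, so a column partition perturbs
p-values at ~1e-16. All reductions on the screening path therefore run in
numba-compiled kernels with plain sequential loops over observations: the
summation order for one triple depends only on n. The file driver also pins
the internal loop orientation from the *total* column counts across all
files, so each chunk computes exactly what the whole-matrix run would.
The one-time kernel compilation takes a few seconds per process.

## Degeneracy and edge cases

- A Gram–Schmidt residual with squared norm ≤ tol × (squared norm of the
  vector being orthogonalized) marks the (x, z) pair degenerate; the
  relative form makes the test scale-free. Default tol = 1e-12. Degenerate
  pairs (e.g. z an affine function of x, or x·z in span{1, x, z}) are
  skipped and counted, never fitted — one pathological pair cannot abort a
  genome-scale run. Zero-variance columns fail the same test at the
  centering step.
- An outcome lying in span{1, x, z} has zero residual variance; its
  denominator test (≤ tol × ssy) marks it skipped for that pair.
- r is clamped into [−1, 1] after division to absorb rounding; |r| = 1
  maps to t = ±∞ and p = 0, which passes any threshold (an exact fit is
  maximally significant).
- p-values use the t survival function, 2·SF(|t|; DF), for accuracy in the
  far tail where 1 − CDF would underflow.
- Records with p ≤ threshold are emitted (inclusive), so hits exactly at a
  published cutoff are never silently dropped. The default threshold is
  1.0 (emit everything); the CLI warns when that implies more than 10⁷
  records.
- Output is sorted by (x column index, z column index, y column index) —
  and by file order first in chunked runs — independent of internal loop
  inversion and worker scheduling.

## Input handling

Missing cells (empty, `NA`, `NaN`, `nan`, case-insensitive) are imputed
with the column mean of the observed values, once at load, so DF = n − 4
always reflects the full row count. A column with no observed values is an
error. Matrices must arrive with identical row-ID order; automatic
reordering is refused (silent sample mix-ups are a classic failure mode in
omics pipelines) and an explicit `align` utility reorders on request.
Row IDs must be unique; duplicate column names are permitted with a warning
and tracked by index internally. Model covariates beyond x and z are out of
scope by design: adjust by residualizing y on the covariates upstream.

## Synthetic data generator

`SimConfig`/`generate_dataset` emulate the shape of a methylation × SNP ×
metabolite scan: X is standard normal (or logit-normal in (0, 1) for
methylation-like values, or 0/1/2 dosages), Z is binomial(2, maf) dosage
with default minor-allele frequency 0.3 (a common post-filter frequency in
cohort scans), Y is Gaussian noise with planted columns following the
interaction model. Defaults: n = 100, 10 columns per matrix, β = (0, 0.2,
0.2, 0.5), σ = 1. The generator does **not** emulate linkage
disequilibrium, correlated methylation blocks, cell-type mixtures or
non-Gaussian metabolite tails — passing tests validate the statistic and
the machinery, not robustness to those real-data features. All randomness
flows through one explicit generator; same seed, same bits.

Monte-Carlo validators: `type_i_error_sim` draws independent null triples
(main effects present, β₃ = 0) and must reject at the nominal rate —
10,000 replicates at n = 100, α = 0.05 give a rate inside [0.040, 0.060],
the 99% binomial band. `power_sim` sweeps β₃ and checks monotone power;
because the screen equals the full-model test, its rejection decisions
coincide with an OLS-based rule replicate by replicate.

## Problem sizes

The acceptance and test runs use desk-scale sizes chosen to exercise every
code path: oracle agreement on 200 triples at n ∈ {10, 50, 100, 500};
determinism on a 60 × (6, 5, 8) design partitioned into 2–3 files per
matrix; a 2 × 10⁶-candidate screen (n = 100, 200 × 100 × 100) that
completes in seconds and is compared against the measured per-model cost of
a general OLS loop on the same machine. Cohort-scale applications (10¹¹
models) are reached through the file-list driver and a stringent threshold.

## Known limitations

- Quantitative variables only; no factors, logistic links, mixed models or
  higher-order interactions.
- Column-mean imputation is crude by intent; use a dedicated imputation
  method upstream when missingness matters.
- The p-value is exact under the Gaussian i.i.d. error model; heavy-tailed
  outcomes inherit the usual OLS t-test caveats.
- Chunked runs re-read each Y file for every (X, Z) file pair; for many
  chunks, order file lists so the largest matrices change slowest.
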