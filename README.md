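# trioscreen

Ultra-rapid, exact p-values for linear-regression interaction terms across
every column triple of three matrices.

## The problem

Multi-omics interaction scans ask whether the effect of one quantitative
variable on an outcome depends on another — for example, whether the
association between a CpG site's methylation level and a blood metabolite
is modified by a SNP genotype. For covariate matrices **X** (n × p₁) and
**Z** (n × p₃) and an outcome matrix **Y** (n × p₂), the model for each
column triple (x, y, z) is

    y = β₀ + β₁·x + β₂·z + β₃·x·z + ε,   ε ~ i.i.d. N(0, σ²)

and the question is the two-sided test of H₀: β₃ = 0. A genome-scale scan
has p₁·p₂·p₃ candidate models — easily 10¹¹ — so fitting each model with a
general OLS routine is hopeless.

`trioscreen` exploits the fact that only β₃ is of interest. Centering the
design and Gram–Schmidt-orthogonalizing {1, x, z, xz} reduces the multiple
regression to a simple regression without intercept: the t statistic of β₃
equals

    t = r·√(DF / (1 − r²)),   DF = n − 4

where r is the partial correlation between y and x·z given {1, x, z}. With
the orthonormal basis built once per (x, z) pair, each outcome column costs
only three inner products, and the resulting p-value is *exactly* the
full-model OLS t-test p-value — the screen is a shortcut, not an
approximation. Records are kept only when p ≤ a user threshold (typically
the Bonferroni cutoff α / p₁p₂p₃), keeping output tractable. Surviving
triples are then refitted in full to recover effect estimates, standard
errors and adjusted R².

The compiled inner loops use a fixed sequential accumulation order, so
results are bit-identical whether matrices arrive whole or as column
partitions across files, and for any worker count.

## Worked example

Generate a synthetic dataset (200 observations; 4 methylation-like
covariates, 3 outcomes, 4 SNP dosage columns) with one planted interaction
(β₃ = 0.6 at x3 × z2 → y1), screen it, and refit the hit:

```sh
$ trioscreen simulate --out-dir demo --seed 7 --n 200 \
      --p1 4 --p2 3 --p3 4 --beta3 0.6 --n-planted 1
$ trioscreen screen --x demo/x.tsv --y demo/y.tsv --z demo/z.tsv \
      --pvalue-threshold 0.001 --output demo/hits.tsv
$ cat demo/hits.tsv
x_name  y_name  z_name  pvalue                  r                   t                  df
x3      y1      z2      6.2676029260358867e-08  0.3729400611646429  5.6271275154681044 196
```

The screen tested all 48 candidate models and kept exactly the planted
triple: the partial correlation between y1 and x3·z2 given {1, x3, z2} is
r = 0.373, giving t = 5.63 on 196 degrees of freedom and p = 6.3·10⁻⁸.
Refitting the survivor recovers the effect size:

```sh
$ trioscreen refit --results demo/hits.tsv --x demo/x.tsv --y demo/y.tsv \
      --z demo/z.tsv --output demo/refit.tsv
```

which reports β₃ = 0.658 (true value 0.6) with the same interaction
p-value 6.27·10⁻⁸ — the shortcut and the full fit are the same test. For a
real scan you would first compute the Bonferroni threshold:

```sh
$ trioscreen threshold --alpha 0.05 --dims 4x3x4
0.00104167
```

Matrices too large for memory can be split column-wise into several files
and screened with `trioscreen screen-files --x-list ... --y-list ...
--z-list ...`, which loads one file triple at a time and produces the same
output as a whole-matrix run.

Covariate adjustment (age, sex, batch, cell composition, ...) is done by
residualizing y on the covariates beforehand and screening the residuals;
the model itself deliberately has no extra covariate slots.

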