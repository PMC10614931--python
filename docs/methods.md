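# Methods

## Model

The generative model is the standard TWAS decomposition.  A mediating
molecular trait has genetic component `T = Σ_k γ_k X_k` over standardized
dosages `X_k`; the target trait is

```
Y = β·T + ε_twas,      ε_twas = Σ_k X_k δ_k + ε,
```

with `δ_k` i.i.d. small polygenic effects (variance `σ_δ²`) and `ε`
independent noise.  The association statistic is the OLS Z-score of `Y` on a
prediction `T̃ = Σ_k γ̃_k X_k` built from noisy weights `γ̃`.  Under a
polygenic null (`β = 0`, `h² > 0`) the Z-score variance is not 1 but

```
var(Z) ≈ 1 + N·h²·Φ,      Φ = (1/M)·(γ̃'Σ²γ̃)/(γ̃'Σγ̃),
```

and under the alternative

```
E[Z²] ≈ 1 + N·h_δ²·σ_Y²/(σ_Y² − τ²β²σ_T²)·Φ + N·τ²β²σ_T²/(σ_Y² − τ²β²σ_T²),
```

where `τ² = var(T)/var(T̃)` is the prediction precision.  Two consequences
drive the design: `τ²` enters only multiplied by `β`, so prediction error
cannot inflate type-I error (error-in-variables), and the inflation term is
linear in `N·h²` with a mediator-specific slope, so a single per-mediator
constant corrects any GWAS once `N` and `h²` are known.  Variance control
divides each Z by `√(1 + N·h²·Φ)` and recomputes the two-sided normal
p-value — a per-mediator analogue of genomic control.

## Simulators and what they emulate

`simulate_genotypes` draws Hardy–Weinberg dosages, Binomial(2, f) per
variant with f uniform on a configurable MAF range (default 0.05–0.5).
Block LD uses a Gaussian-copula construction: two latent haplotype vectors
per individual with an exchangeable (or explicit) latent correlation,
thresholded at the allele-frequency quantile.  Because thresholding
attenuates correlation, the latent value is calibrated by solving the
bivariate-normal orthant equation (at the block's mean MAF) so the realized
dosage correlation approximates the requested one; non-PSD specifications
are rejected naming the offending block.  This emulates LD structure, not
real haplotypes: no population structure, relatedness, imputation noise, or
realistic LD decay.  Tests passing on these panels therefore demonstrate
the statistical mechanics of inflation and its correction, not robustness
to those real-data complications.

`simulate_polygenic_trait` draws `δ` i.i.d. over *all* panel variants
(infinitesimal model) and by default rescales the genetic component to hit
the target `h²` exactly in-sample.  The exact rescale removes one Monte
Carlo noise source from Φ estimation; expectation-only scaling
(`exact_scale=False`) is available.  Both `δ` and `ε` are redrawn each
replicate.  Student-t effect and noise distributions (default df = 5:
finite variance, visibly heavy tails) support robustness checks; t draws
are scaled to unit variance so the h² budget is preserved.

`simulate_alternative_study` builds `T` from the true weights (rescaled to
`σ_T²`), adds a genotype-spanned prediction-error component orthogonalized
against `T` in-sample and scaled so `var(T)/var(T̃) = τ²` exactly, and
forms `Y = β·T + b + ε` with the polygenic background `b` rescaled to
`h_δ²·σ_Y²` and `ε` supplying the remaining variance (the simulator rejects
specs where `σ_Y²(1−h_δ²) − β²σ_T² ≤ 0`).  `h_δ²` is interpreted as the
*fraction* of `var(Y)` that is polygenic, which makes the `β = 0` case
coincide with the polygenic-null simulator.

## Estimating Φ

`theoretical_phi` evaluates the quadratic-form ratio directly; weight
vectors covering a subset of variants are zero-padded by variant id.  It is
exact but needs `Σ` and `M`, which are unavailable for real data, so it
serves as the oracle for the empirical estimator on synthetic fixtures.

`estimate_phi_empirical` mirrors practice: for each cell `(N, h²)` of a
`SimulationGrid` it subsamples `N` individuals from the reference panel
without replacement, standardizes the subsample, simulates
`n_reps_per_cell` polygenic null traits, computes the Z² of every mediator
against every trait (a vectorized equivalent of the scalar association
test, verified equal in unit tests), and regresses the per-cell mean Z² on
`N·h²`.  The slope is `Φ̂`, clamped at 0 with a `clamped` flag (negative
slopes arise by sampling noise when Φ ≈ 0); the free intercept is a
calibration diagnostic that should sit near 1.  Default grid:
`N ∈ {1000, 2000, 5000} × h² ∈ {0, 0.2, 0.5, 0.8}`, 300 replicates per
cell — a full single-mediator estimate runs in about a second and a
500-mediator batch (traits shared across mediators, as when annotating a
model database) in a few seconds on one CPU; heavier grids simply scale
these factors.

Cell means are heteroskedastic (`var(Z²) ≈ 2·var(Z)²` grows with `N·h²`),
so the slope and intercept standard errors propagate the *empirical*
per-cell standard errors of the mean Z² through the OLS weights rather than
using the pooled homoskedastic formula, which understates the slope
uncertainty by roughly half on the default grid.  The point estimate stays
equal-weight OLS (matching the plotted-cell-averages convention);
inverse-variance weighting is available via `weighted=True`.

## Numerical choices

- Standardization uses ddof = 0; monomorphic columns are an error.
- The association test always includes an intercept; p-values use the
  standard-normal reference (`t_reference=True` switches to t(n−2); at the
  sample sizes of interest the difference is negligible).  Constant
  predictors and numerically perfect fits (RSS below 1e−24 of the trait sum
  of squares) are rejected, not returned as infinite Z.
- "Sample variance of Z" is the mean of Z² (variance about zero), matching
  the average-Z² inflation statistic; the mean-centered variant is an
  option.
- The chi-square-mean reference interval uses the normal approximation
  `1 ± z·√(2/n)` by default, with exact chi-square(n)/n quantiles as an
  option (they differ by < 0.005 at n = 1000).
- Φ clamping: `phi = max(phi_raw, 0)`; the raw slope and its SE are always
  reported.
- QQ confidence bands are pointwise beta-distribution intervals for uniform
  order statistics.

## Design decisions

- The grid regression fits a free intercept and reports it as a diagnostic
  rather than forcing intercept = 1; forcing it would fold miscalibration of
  the null machinery into Φ̂ silently.
- `M` is taken as the number of simulated causal variants in synthetic
  settings (the infinitesimal model makes every panel variant causal); for
  real data it is the user's input, and the empirical estimator exists
  precisely so that `M` and `Σ` never need to be known.
- The correction accepts externally computed Z-scores: the contribution is
  the variance model, which applies to any TWAS-style Z regardless of the
  software that produced it.  Summary-statistic TWAS is therefore not
  re-implemented.
- Missing-Φ rows are left uncorrected and flagged by default (dropping is
  an option); silent row loss is worse than an annotated gap.
- `write_phi` into a model store requires a matching build identifier, so Φ
  values can never be mixed across model builds.
- Binary target traits are accepted with a logged warning: the linear-model
  correction is a balanced-design approximation and no effective-N
  adjustment is applied.
- Uniformity is assessed by a KS test at a fixed level; this is a proxy for
  the visual QQ-alignment criterion and is documented as such.
- h² is a point estimate supplied by the user (e.g. LD score regression);
  propagating its uncertainty into corrected p-values is out of scope.

## Limitations

- The infinitesimal additive model is assumed throughout; traits with a few
  large-effect loci or non-additive architecture are outside the variance
  model, and the correction is then a first-order approximation.
- The correction does not address cis horizontal pleiotropy with large
  effects, co-regulation, or LD contamination — complementary methods exist
  for those.
- Φ estimation quality depends on the reference panel matching the GWAS
  population's LD; panel mismatch is not modeled here.
- The acceptance-style checks use panels of up to 5000 individuals and 500
  to 999 variants with identity LD, where the closed form Φ = 1/M is known;
  they validate the estimator and correction machinery, not genome-scale
  performance.
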