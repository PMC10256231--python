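# Methods

This note documents the models implemented in `fieldomics`, the choices
made where the design was genuinely open, and what the synthetic-data
generator does and does not emulate.

## The setting

A single field trial of genetically near-uniform winter oilseed rape:
plants on a regular grid (default 10×10, 0.5 m spacing), border plants
excluded, interior plants individually RNA-sequenced once (leaf tissue,
autumn) and phenotyped repeatedly through to harvest. Sample sizes are
therefore fixed by the field: ~62 plants, with a handful of technical
sequencing repeats spread over 3 batches. All inference has to work at
n ≈ 60 and respect the spatial dependence induced by shared soil,
drainage and micro-climate.

## Synthetic trial generator (`fieldomics.simulate`)

The generator is first-class, tested code: it defines the conditions under
which every estimator in the package is validated.

**Layout.** `make_field_design` builds the grid, flags the border
(first/last row/column) and knocks out a fraction of positions to mimic
emergence failures; the missing count is a fraction of all positions,
realized among interior plants (border plants never enter the analysis
set). Defaults (10×10, 0.5 m, 2% missing) give the 62-plant analysis set
of the motivating trial.

**Latent micro-environment.** One multivariate-normal field over the
analysis plants with the Gaussian covariogram
`Σ_ij = σ²(ν·I + (1−ν)·exp(−(d_ij/r)²))` — the same family the
association model assumes, so recovery tests have a well-defined target.
Defaults ν = 0.3, r = 1.0 m, σ² = 1: correlation reaching 2–3 plant
spacings, with a third of the variance unstructured.

**Expression.** Gene i, sample j:
`k_ij ~ NB(s_j · 2^(b_batch) · 2^(β_i0 + β_ip), α_i)`.
Per-gene log2 baselines are uniform on (3, 12) (spanning shallow to deep
expression), batch effects on the non-reference batches are
log2-normal(0, 0.3), library size factors uniform on (0.7, 1.4), and a
random 20% of plants receive a technical-repeat sample sharing the plant
effect but drawing its own counts, batch and size factor. Plant effects
are `loading_i · latent + N(0, 0.45)` with loadings N(0, 0.7): total
between-plant log2 sd ≈ 0.8, i.e. typical plant-to-plant expression
differences of 50–80%, the magnitude that makes single-plant profiling
informative in the first place. Dispersions α are uniform on
(0.005, 0.05), the technical (within-plant) overdispersion scale —
biological variation between plants lives in the plant effects, not in α.

**Causal structure.** A random subset of genes forms the causal set for
the phenotypes. These genes additionally share a per-plant *module score*
(iid N(0,1), weight 1.0): they behave as one co-expressed pathway. This
matters statistically: a trait driven additively by k independent genes
leaves each gene a marginal signal of order 1/√k, unrecoverable at
n ≈ 60; a co-expressed module is both biologically the expected structure
and the regime in which marginal screening can work.

**Phenotypes.** The quantitative trait is
`y_p = Σ_c coef_c·β_{c,p} + λ·latent_p + ε_p` (λ = 0.5, ε sd = 0.5),
built from the *true* plant effects so recovery is well defined. A count
trait is NB around the exponentiated standardized signal. The ratio trait
is emitted as a (numerator, denominator) pair with
`n_p ~ N(d_p·exp(β0 + β1·x_p), σ²)` — the generative form of the
conditional log-link model.

**Growth.** Per-plant beta-sigmoid parameters: initial height 10–30 cm,
final height 120–160 cm, maximal growth at 850–1000 cumulative GDD from a
September sowing and growth ending 150–250 GDD later. With the synthetic
temperature series (sinusoidal annual cycle, mean 10 °C, amplitude 8 °C,
sd-2 °C daily noise) this places the steep rise inside the dense spring
measurement window (13 points over DAS 189–231) and the plateau before
the final harvest measurement at DAS 278, matching the trial design. The
measurement layout leaves a thermal-time gap between the last spring
point and harvest, so the end-of-growth parameter is only weakly
identified under the field schedule; the dedicated recovery study
therefore uses a 14-point design spanning the whole curve (ages 30–1400
GDD), which is the regime the recovery claim refers to.

**What the generator does not emulate.** Read-level artifacts (mapping
bias, multi-mapping, 3′ bias), count outliers, genotypic segregation,
temporal phenotype correlations beyond the growth curve, and
non-Gaussian micro-environment fields (e.g. sharp soil boundaries).
Passing tests demonstrate calibration and recovery *under the assumed
model family*; on real data the covariogram family and NB error model are
approximations.

**Randomness.** One master seed; each stage (layout, latent field, gene
parameters, counts, phenotypes, growth) draws from a named SeedSequence
substream, so stages are reproducible in isolation.

## Normalization (`fieldomics.rlog`)

Size factors use the median-of-ratios estimator over genes with nonzero
counts in every sample (geometric means over positive counts if no such
gene exists), rescaled to geometric mean 1.

Dispersion is a method-of-moments estimate, floored at 1e-8. Without
metadata it is the classical across-sample estimator; with metadata the
*residual* dispersion is estimated from within-plant (technical-repeat)
variation only, because under a design with per-plant coefficients the
repeats carry all residual degrees of freedom — the across-sample
estimator would absorb the biological plant variance into α and
over-weight the prior. The moment equation corrects for the Poisson
contribution of each sample's size factor. An ML refinement was
considered and rejected: at ~12 repeat pairs per gene the moment
estimator is within the accuracy that matters for shrinkage weighting,
and it is orders of magnitude faster.

The per-gene model maximizes the NB likelihood with a flat prior on the
intercept and batch coefficients and a zero-centered normal prior on the
plant coefficients, by L-BFGS with the analytic gradient (log2-scale
coefficients; an exact Poisson branch replaces the NB terms when
α < 1e-6, where 1/α would destroy the gammaln differences). Failures fall
back to an intercept+batch fit with plant effects pinned at zero,
flagged. A prior variance below 1e-8 is treated as the exact zero-prior
limit (plant effects identically zero) rather than fought numerically.

The prior variance is set once, globally: unshrunken per-plant log2 fold
changes are computed from `log2(k/s + 0.5)` relative to each batch's mean
(not the grand mean, so batch effects do not inflate the prior), repeats
averaged, and the 95th percentile of their absolute values is matched to
the 95th percentile of a zero-mean normal. The quantile is a parameter;
0.95 keeps the prior wide enough that genuine plant effects are damped,
not erased.

Two outputs: the rlog matrix `β_i0 + β_ip` (batch-free, repeats
collapsed, log2 scale) for association and prediction, and normalized
counts `k_ij/(2^batch·s_j)` with repeats averaged (linear scale) for the
variability statistics.

Caveats established by the tests: shrinkage is a strict per-gene norm
contraction but not exactly coordinate-wise monotone (per-plant shrinkage
factors depend on each plant's counts, and the intercept recenters), and
batch-scaling invariance of the rlog output is tight only for
well-measured genes — multiplying near-zero counts by a constant
genuinely changes their information content.

## Spatial statistics (`fieldomics.spatial`)

Moran's I with binary queen weights (grid positions differing by ≤1 in
both coordinates) or inverse-distance weights (`1/d_ij`, not
row-standardized, mirroring the comparison method it reproduces). Weights
are rebuilt per phenotype on the plants with observed values.

The permutation test reports the upper-tail pseudo p
`(1 + #{I_perm ≥ I_obs})/(1 + n_perm)` — positive autocorrelation is the
alternative of interest; a two-sided option doubles the smaller tail. The
parametric test uses E[I] = −1/(n−1) and the closed-form normality
variance from S1, S2; on a saturated graph (every pair connected) that
variance is exactly zero and I is constant at −1/(n−1), so the degenerate
branch returns p = 1 when I equals the null mean.

Category statistics: two-sided Mann–Whitney U on rank positions (normal
approximation, tie-corrected) and upper-tail hypergeometric enrichment,
both BH-adjusted across categories.

## Variability (`fieldomics.variability`)

CV is reported in percent with the (n−1) sd. The mean–CV² trend
`CV² = a/x̄ + b` is a gamma-family GLM with identity link over genes
expressed (normalized count > 0) in ≥ 10 samples; CV² is dimensionless
(fractional), stated in the output headers. On GLM failure a robust
soft-L1 least-squares fit stands in. normCV is `log2(CV²/trend(x̄))`.
Outliers: |x − median| > 3·1.4826·MAD; when the scaled MAD is zero, any
value different from the median is flagged (the limit-consistent
extension). Outlier removal affects only the variability/normality
reporting, never association or prediction inputs. Normality screening
passes at p > 0.01 on both Shapiro–Wilk and Anderson–Darling (the latter
with table-interpolated p-values).

## Growth curves (`fieldomics.growth`)

Thermal time `t(i) = Σ_{j≤i} max(T_j − T_b, 0)`, T_b = 5 °C. The
beta-sigmoid
`h(t) = h0 + (hmax−h0)(1 + (te−t)/(te−tm))(t/te)^{te/(te−tm)}` for
t < te, clamped at hmax beyond te, is fitted by bounded trust-region
least squares with te parametrized as tm + Δ (Δ > 0) so the ordering
constraint always holds. Starting values: h0 = min height, hmax = max
height, tm = age of the largest observed increment, te = 1.1× the last
age. Fits are flagged unconverged when the optimizer fails or the curve
degenerates (hmax ≈ h0, parameters at bounds). The maximal growth rate is
the analytic derivative at tm (validated against central differences);
GDD→calendar inversion interpolates linearly within days, and days after
sowing roll over the year boundary via the contiguous day index.

## Spatial mixed model (`fieldomics.lme`)

`y = β0 + β1 x + ε`, `ε ~ N(0, σ²R(ν, r))` with the Gaussian
correlogram. (ν, r) are optimized by ReML on the (logit ν, log r) scale —
a 5×5 coarse grid seeds 5 quasi-Newton restarts — with (β0, β1, σ²)
profiled out by GLS at every step. Wald tests on β1 use a t reference
with n − 2 degrees of freedom (the reference distribution is a choice;
n − 2 matches the fixed-effect count and is slightly conservative).
Optimizer failure falls back to ordinary regression, flagged. Screening
z-scores each feature across all included plants, drops plants with
missing phenotype, BH-adjusts across features, and excludes from the BH
family only features unfittable even by the fallback.

Cross-validated single-feature prediction uses fixed effects only
(β0 + β1 x on the test plants): conditioning test predictions on training
residuals through Σ (kriging) would change the contract from "how
predictive is this gene" to "how predictive is this gene plus the field
map", and the simpler contract is the one comparable with the multi-gene
models. Inside cross-validation the z-scoring is recomputed on training
folds only, avoiding leakage; the full-data z-scoring used in screening
is a deliberate, separate convention.

Ratio phenotypes: `n ~ N(d·exp(β0+β1x) − c, σ²W)` with c ≥ 0 only in the
offset variant (c is log-parametrized, strictly positive, reaching 0
smoothly; a second start from a larger c guards the weakly identified
offset direction). W is the identity, the Gaussian correlogram, diag of
the fitted mean (variance linear in the estimate; an sd-linear
alternative sits behind a flag), or the symmetric combination
`V^{1/2} R V^{1/2}`. σ² is profiled; optimization is Nelder–Mead;
negative fitted means are rejected by the objective. The Wald standard
error comes from a central-difference Hessian of the profiled negative
log-likelihood over the mean parameters.

## Prediction protocol (`fieldomics.predict`)

9 repeats × 10 folds = 90 splits; fold assignment is a uniform random
partition per repeat (continuous outcomes, no stratification), seeds
base_seed+0..8. Selection runs on the training fold only. Selectors:
median rlog > 0; Spearman filter at BH q ≤ 0.01 falling back to raw
p ≤ 0.001; HSIC lasso — centered, Frobenius-normalized Gaussian-kernel
Grams (bandwidth 1 on z-scored variables) for each candidate and for the
outcome, a nonnegative lasso path over the vectorized Grams, returning
the largest active set not exceeding 200 features, after an optional
variance-based prefilter of the candidate pool (the prefilter size, 5000
by default, is configuration). Learners: elastic net with mixing
∈ {0.1, 0.5, 0.7, 0.9, 0.95, 1.0} and a 100-point penalty path chosen by
4-fold inner CV on training-fold-standardized features; and a 1000-tree
regression forest considering all features per split, with
(max depth ∈ {1,2,5,10,20,50}) × (min leaf ∈ {1,2,5}) chosen by
out-of-bag score.

Metrics: out-of-sample R² per split uses the test-fold mean in the
denominator (so a fold the model cannot beat locally scores ≤ 0); pooled
R²/PCC are computed on each repeat's concatenated test predictions, and
medians are taken over the 90 splits / 9 repeats (even-count medians are
midpoint averages). Importances are |coefficient| (elastic net) or
impurity importance (forest); per-feature medians are taken over the
splits where the feature was selected — unselected splits are missing,
not zero, with the selection frequency reported separately.

The permutation baseline retrains the full selection+fit pipeline on 90
label permutations, one random 90/10 split each, and reports the 95th
percentile (linear interpolation) of the permuted scores; a model earns
its star when the real median test R² exceeds it. Because the real
statistic is a median of 90 scores while the baseline draws are single
splits, the criterion is conservative under the null — its null pass rate
is below the nominal 5%, which the calibration test checks as an upper
bound.

## Problem sizes

The test suite and the acceptance script run the full protocols at
reduced but statistically meaningful sizes chosen as the package's own
validation design: 60–300 genes, the 62-plant layout, 150–300 Monte-Carlo
replicates for calibration studies, 50 generator replicates for the star
criterion (with a single-mixing, short-path elastic net inside the
calibration loops — the protocol's behavior under permutation does not
depend on the hyperparameter grid's resolution), and 100–200 simulations
for growth recovery. The defaults of the library itself are the full-size
ones documented above.

## Known limitations

- ReML plug-in Wald inference is mildly anticonservative when (ν, r) are
  weakly identified (small n, smooth fields); the calibration test bounds
  the excess at ≈1–2 points around the 5% level on the 62-plant layout.
- The HSIC lasso solves the nonnegative lasso on O(n²)-row design
  matrices; it is intended for n of order 10², not 10⁴.
- The log-link ratio model's offset c is weakly identified when β1 is
  small and d has little spread; the two-start heuristic reduces but does
  not eliminate boundary solutions.
- `batch_normalized_counts` divides by point estimates of batch effects;
  genes with near-zero counts in a batch inherit that estimate's noise.
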