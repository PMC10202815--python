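# Methods

## The scientific problem

Partners resemble each other in many traits. Three mechanisms can
produce that resemblance: direct partner choice (assortative mating on
the trait), confounding (assortment on a correlated trait or shared
environment), and post-pairing convergence. `couplemr` implements a
cross-partner Mendelian-randomization (MR) framework that separates
these mechanisms on synthetic couple cohorts: the exposure is a trait of
one member of a couple (the *index*), the outcome a trait of the other
(the *partner*), and genetic variants of the index serve as instruments.

## The structural couple model

Each person carries a focal trait

```
X = g·G + e·E,        g² + e² = 1,
```

with `G` a standardized additive genetic score over `k` independent
biallelic SNPs and `E` a unit-variance environment, so the heritability
is `g²` (default 20%: `g = √0.2`, `e = √0.8`).

**Parental (dynastic) effects.** Both members of a couple are offspring
of a simulated parental couple. Parental aggregates are the rescaled
means, e.g. `X_P = (X_M + X_F)/√(2(1 + cor(X_M, X_F)))`, which keeps
them at unit variance. The offspring environment receives

```
E_O = s_G·G_P + s_E·E_P + s_X·X_P + residual,
```

with the residual rescaled so `Var(E_O) = 1`. Alleles are transmitted
Mendelianly (one per parent per locus). Parental effects induce a
genotype–environment correlation in the offspring,

```
c = (1/√2)(s_G + s_X·g),
```

which is the single quantity through which dynastic effects bias
cross-partner MR. Two consequences worth noting: the scaled mean
parental score correlates with the offspring score at `1/√2` (exactly
when parents are unassorted; up to a term of order `ρ/4` when the
parental generation is itself assorted at correlation `ρ`, which is why
the identity is checked at a 0.02 tolerance rather than Monte-Carlo
precision), and the offspring trait variance is `1 + 2·g·e·c` (exactly 1
whenever `s_G = s_X = 0`). Only one parental generation is simulated;
assortment is not iterated to equilibrium.

**Couple formation.** Couples form under up to three simultaneous
*direct assortments*: on the genetic score (target correlation `r_G`),
the environment (`r_E`) and the trait (`r_X`). We formalize "pairing
such that the targets are met" as a conditional-independence Gaussian
copula: the cross-partner covariance of the feature vector `F = (G, E)`
is

```
K = Σ_channels r_v · Cov(F, v) Cov(v, F)ᵀ / Var(v),   v ∈ {G, E, X},
```

i.e. all cross-partner dependence flows through the matched variables.
Pairing is realized by whitening `F`, taking the SVD of the whitened
`K`, drawing per-index-person Gaussian targets along the singular
directions, and matching partner candidates to targets by rank
(one-dimensional: exact rank matching; higher rank: nested quantile
strata, a cheap optimal-transport surrogate whose correlation error
vanishes with the stratum count ~ √n). Infeasible target combinations
(singular value > 1, or an implied total couple correlation outside
[-1, 1]) raise an error instead of silently clipping. Marginal
distributions are untouched by construction.

Under this mechanism the realized cross-partner correlations follow the
closed forms

```
cor(X_i, X_p) = r_X + r_E·e² + r_G·g²
cor(E_i, E_p) = r_E + r_X·e² + r_G·c²
cor(G_i, G_p) = r_G + r_X·g² + r_E·c²
```

to first order. The closed forms neglect O(r·c) cross-terms that any
internally consistent pairing mechanism produces; at the most extreme
corner we explore (`r_X = 0.2, r_E = 0.3, s_X = 0.3`) the genotype
formula deviates by ≈ 0.013 while the trait/environment formulas and
the MR expectation deviate by < 0.005. Property tests therefore pin the
formulas at moderate parameter points with tolerance `3/√n`.

## The analytic bias model

The per-score regression expectations are

```
E[β_index]   = g + c·e
E[β_partner] = (g + c·e)·r_X + r_G·g + c·(r_E·e)
E[α] ≈ E[β_partner]/E[β_index] = r_X + (r_G·g + c·r_E·e)/(g + c·e)
```

so the MR bias is `E[α] − r_X`. The ratio-of-expectations form is
treated as the definition; its gap to the exact estimator expectation is
quantified empirically (simulated IVW agrees within max(0.02, 2 MC se)
over the explored grid, with a measured gap of ≈ 0.002 at the corner).
Of the five violation channels, `s_E` (parental environment on offspring
environment) opens no genotype path and produces exactly zero bias — a
tested invariant. Violation magnitudes induced by a genetically
correlated secondary trait Y follow
`r_G = (g·r_G(X,Y))²·r_Y` and `s_G = g·r_G(X,Y)·s_Y`, which is why
genetic-side violations are an order of magnitude weaker than
environmental ones over the ±0.3 grid.

## Estimators

* **IVW**: `α̂ = Σ β_x β_y σ_y⁻² / Σ β_x² σ_y⁻²`, `Var(α̂) = 1/Σ β_x² σ_y⁻²`
  — identical to no-intercept WLS with weights `σ_y⁻²` (tested against
  statsmodels to 1e-10). Wald ratio at k = 1.
* **Cochran's Q** on Wald ratios with delta-method weights `β_x²/σ_y²`;
  p from χ²(k−1), undefined (NaN, not fabricated) at k = 1.
* **Standardization** of summary effects via the z-to-correlation
  conversion `b* = z/√(n − 2 + z²)`, exact for simple regression on
  standardized variables; `se* = b*/z` (`1/√(n−2)` at z = 0).
* **Steiger filter**: remove a SNP iff |outcome effect| > |exposure
  effect| *and* the one-tailed normal test of the difference (variance
  `se₁² + se₂²`, independent samples) has p < 0.001. The normal form is
  used because exposure and outcome effects come from different samples
  in this design.
* **Fixed-effect meta-analysis** pools SNP effects across sexes *before*
  MR (limits weak-instrument bias); infinite se ⇒ zero weight.
* **Sex-heterogeneity filter**: per-SNP two-sample Z test, Bonferroni at
  0.05/k.
* **MVMR**: weighted no-intercept multiple regression of outcome effects
  on the exposure-effect columns. Exposures with identically zero
  effects are dropped (nested model, coefficient 0, se ∞); genuine rank
  deficiency raises a collinearity error.
* **Instrument selection**: p < 5e-8, then greedy LD pruning in
  ascending-p order at r² < 0.001 against an explicit LD matrix
  (identity when loci are simulated independent). Physical-distance
  clumping is deliberately replaced by pure r² pruning.
* **Effective number of tests**: Li–Ji eigenvalue method on the absolute
  trait correlation matrix (eigenvalues clipped at 0 with a warning if
  the input is not PSD, and rounded to 10 decimals before the
  floor/fraction split to avoid spurious ±1 contributions at integer
  eigenvalues).

## Single-trait pipeline

Couples are identified from household records (exactly two unrelated
opposite-sex members, both partner-coded; per-rule exclusion counts are
logged). Phenotypes are inverse-normal transformed (Blom offset
`(rank − 0.375)/(n + 0.25)`, average ranks for ties). Traits are
screened at couple correlation > 0.1 and ≥ 5 valid instruments. The
couple MR is estimated per sex and pooled at the SNP level; the raw
correlation (se `√((1−r²)/(n−2))`) is compared to the MR estimate with
a two-tailed Z test treating the two as independent. Convergence is
probed by splitting couples into 5 quantile bins of time-at-address or
median age (ties kept within one bin) and regressing per-bin estimates
on bin medians with weights 1/se (inverse-SE, not inverse-variance — a
deliberate convention of the trend test).

On the calibration of the correlation-vs-MR Z test: when r̂ and α̂ are
computed on the same couples their errors correlate at ≈ √h² (both are
regressions of the partner phenotype on correlated index variables),
making the test conservative (true type-I ≈ 1.6% at h² = 0.2 instead of
5%). The calibration experiment in the test suite therefore draws the
correlation and the couple GWAS from independent couple samples, where
the independence assumption holds and the nominal 5% rate is recovered.
Applied to fully overlapping samples the test errs on the conservative
side.

## Confounding decomposition

A confounder Y (within-person effect `α_{y→x}`, cross-partner effect
`α_{y_i→y_p}`) induces couple correlation `C = α_{y→x}²·α_{y_i→y_p}`.
Candidates pass three sequential filters (same-person MR significant at
0.05/Meff after Steiger pre-filtering; within-couple MR significant at
0.05/#remaining; |correlation with X| < 0.8, computed on the pooled
sample), are greedily pruned at r² < 0.1 prioritizing larger |C| (ties
by trait id), and the surviving C values are summed; `Var(C)` uses
`Var(A²) = 4μ²σ² + 2σ⁴` and the independent-product variance formula,
and `Var(C_sum)` is the sum of variances (validated against Monte-Carlo
within 2%). The confounding ratio is `C/cor(X_i, X_p)`, with orthogonal
coordinate pairs summed before dividing.

## Cross-trait path decomposition

For a trait pair (X, Y) the total cross-partner effect ω (couple MR of
X_i on Y_p, Steiger-filtered instruments, pairs with |correlation| ≥ 0.8
refused) decomposes into the exposure-assortment path
`γ = α_{x_i→x_p}·α_{x→y}` and the outcome-assortment path
`ρ = α_{y_i→y_p|MVMR}·α_{x→y}` (the MVMR `Y_p ~ Y_i + X_i` strips the
residual X path). Standard errors of the products use the independent-
product variance identity. Across pairs, ρ is residualized on γ by OLS
*with intercept*, sign-mismatched pairs are removed before the paired t
test, and ω is regressed through the origin on γ + ρ_resid with the
uncentered R² convention (R² = 1 − RSS/Σω²). The through-origin
regression is unweighted.

One structural subtlety: in an outcome-assortment-only design the
single-trait couple MR of X is itself confounded by Y-assortment
(exactly the mechanism the C statistic describes), so γ's generative
value is `r_Y·α³` rather than exactly zero. The recovery tests assert
that oracle value; at the default design (α = 0.3, r_Y = 0.2) it is
0.0054, an order of magnitude below ρ.

## Synthetic data: what it does and does not emulate

The generator reproduces the statistical skeleton the analysis relies
on: polygenic architecture with exchangeable SNP effects, Hardy–Weinberg
genotypes (optional AR(1) LD for exercising the pruner), Mendelian
transmission, simultaneous direct assortments, dynastic effects,
within-person causal networks with unit-variance traits, direct
partner-to-partner injections (e.g. secondhand-smoke-like terms), and
sex labels/age/time-together columns with realistic ranges. It does not
emulate: real LD structure or population stratification, binary/ordinal
measurement scales, missingness patterns, measurement noise (a noise
parameter would attenuate correlations by Var(y)/(Var(y)+s²) but is not
part of the defaults), age-dependent assortment, or trait-specific
effect-size distributions. Passing tests therefore demonstrate
correctness of the estimators and the internal consistency of the
model, not robustness to those real-data complications.

## Default parameters and problem sizes

| Parameter | Default | Meaning |
|---|---|---|
| h² | 0.2 | trait heritability (g = √0.2) |
| r_X | 0.2 | direct trait assortment |
| r_G, r_E, s_G, s_E, s_X | 0 | violation channels, off by default |
| n_couples | 50,000 | reference cohort size |
| n_snps | 100 | instrument panel, MAF 0.3 |
| p_instrument | 5e-8 | genome-wide significance screen |
| r2_prune | 0.001 | instrument LD pruning |
| steiger_p | 0.001 | directionality filter |
| screen_r / min_ivs | 0.1 / 5 | trait screen |
| confounder corr cap / prune r² | 0.8 / 0.1 | confounder filters |
| n_bins | 5 | convergence bins |

Validation experiments use 50,000 couples × 100 SNPs (reference and
bias-grid checks), 50,000 × 60 per trait (two-trait designs), and 500
replicates of 3,000 × 10 for the calibration study — sizes chosen so
Monte-Carlo error is well below the effects under test while the whole
suite stays fast on a single CPU.

## Numerical choices and degenerate inputs

Seeds propagate through `numpy.random.Generator` objects; pipeline
stages derive named substreams from the master seed via `SeedSequence`,
so identical configuration and seed reproduce byte-identical outputs.
Tabular artifacts are TSV with `%.17g` floats; the summary-statistics
reader converts numbers elementwise with Python `float()` because
pandas' fast parser does not round-trip the last ulp. Degenerate inputs
fail loudly and specifically: zero-variance phenotypes, all-zero
exposure effects, infeasible assortment targets, constant genotype
columns (excluded per SNP), k = 1 heterogeneity p-values (NaN), and
empty instrument sets after screening (trait skipped with a reason).

## Known limitations

Single parental generation (no assortment equilibrium); the closed-form
correlation expectations are first-order (documented deviation at
extreme parameter corners); the corr-vs-MR Z test ignores estimate
dependence on overlapping samples (conservative); trait networks do not
combine with parental effects; no pleiotropy-robust MR variants
(MR-Egger, weighted median) — the framework studies bias of plain IVW
by design.
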