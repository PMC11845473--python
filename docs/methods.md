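# Methods

## Model and assumptions

The core model treats an observed national access rate C (proportion in
[0, 1], per country × year × service × quality level) as Gaussian around a
logistic mean:

    η  = β₀ + Σᵢ Cᵢ Xᵢ + C_d X_d
    P  = 1 / (1 + exp(−η))
    C  ~ Normal(P, σ)

The logistic link keeps the mean in (0, 1) and encodes diminishing marginal
gains near full coverage; the error is an *untruncated* Gaussian on the rate
scale, so observed rates of exactly 0 or 1 — and improvement outcomes
slightly below 0 — are ordinary data, not boundary cases. This is a
deliberate modelling choice with a known cost: the likelihood can place mass
outside [0, 1], which is harmless at σ ≈ 0.05 but would be questionable for
very noisy data.

Rows are country-years, treated as exchangeable; there are no hierarchical
country effects, no temporal correlation between a country's two rows, and
no spatial structure. The year dummy X_d (0 = earlier year, 1 = later year)
is the only time structure, so C_d is interpretable as the adjusted
cross-year shift on the logit scale at fixed covariates.

### Priors

Normal(0, 50) on the intercept and every coefficient, and Normal(0, 50)
truncated to (0, ∞) on σ — a literal "all parameters normal" reading that is
practically flat for coefficients of magnitude ≲ 3. A flat positive σ prior
is available as a config switch (`PriorSpec.sigma_prior="flat"`); at these
data sizes the two are indistinguishable.

### Estimation

Each declared chain is an independent affine-invariant ensemble (emcee),
seeded from a `SeedSequence` spawn of the run seed, so results are exactly
reproducible and independent of stage execution order. Per-chain geometry:
`iterations` counts retained-plus-warmup draws; the ensemble uses
`max(2·ndim + 2, 20)` walkers (configurable) with at least 150 warm-up steps.
Walkers initialize at the logit-scale least-squares solution, spread at twice
its standard errors, so the ensemble starts near-posterior even for
near-noiseless data; with zero data rows the walkers initialize from the
prior itself, which is then the exact posterior (used by the
prior-dominance test). Defaults follow standard practice for this analysis:
10,000 iterations, 4 chains, 2,000 warm-up; tests and the acceptance script
use a reduced 2 × 3,000 geometry that leaves posterior summaries within
Monte Carlo noise of the full setting on these problem sizes (150 country
panels, ≤ 6 parameters).

Convergence is the classic (rank-free) split-chain Gelman–Rubin statistic,
√(((n−1)/n·W + B/n)/W) with each chain split in half; the fit is flagged
converged when every parameter's R-hat < 1.10. Non-convergence warns and
returns `converged=False` rather than raising — exploratory practice —
with a strict pipeline mode that aborts instead. Summaries pool post-warmup
draws across chains: posterior mean, central (equal-tailed) 2.5/97.5%
quantiles, and a significance flag when the interval excludes 0. No
multiple-testing adjustment is applied anywhere; significance is
per-parameter by design.

## Covariate handling

Per-capita GDP, GDP PPP and per-capita renewable internal freshwater
resources are log₁₀-transformed (they must be strictly positive; non-positive
records are excluded at read time with a warning). Urban population rate and
democracy index enter untransformed. Each factor column is then z-scored
(mean 0, sd 1, n−1 denominator) over the stacked two-year rows, *after*
transformation. Pooled (rather than per-year) normalization keeps one scale
for both dummy levels so C_d is a pure year contrast; per-year normalization
is a switch. Because z-scoring absorbs affine rescalings, the choice of log
base is provably irrelevant (tested to 1e−12).

Complete cases are country-years: a country observed in only one year still
contributes that row; a stricter both-years rule is a switch. Missing data
are dropped and counted, never imputed. The democracy index starts in 2006,
so each country's 2006 value is carried to 2000 (existing 2000 values are
never overwritten).

The "basic or higher" quality level is derived, not observed: where a
cumulative `at_least_basic` row exists it is used directly (in JMP-style
ladders it already equals basic + safely managed); otherwise
`safely_managed + basic` is summed, and a sum exceeding 1 + 1e−9 is an error
because it signals double counting. Summing all three categories would
double-count and was rejected; the policy is switchable
(`policy="sum_components"`) for data whose ladder semantics differ.

Multicollinearity is reported (never acted on) via variance inflation
factors, VIF_j = 1/(1 − R²_j) from OLS of column j on the others plus an
intercept, with perfect collinearity reported as `inf` rather than raised.

## The improvement statistic

P₂ = (C_2020 − C_2000)/C_2020 is the attributable proportion of 2020
coverage built since 2000. It is scale-invariant, increasing in C_2020,
decreasing in C_2000, and undefined at C_2020 = 0 (status
`undefined_zero_denominator`). Countries with P₂ < −0.05 — strictly below,
so −0.05 itself is retained — are excluded as implausible declines; retained
negative values enter the Gaussian likelihood untouched. Covariates for the
P₂ regression are 2000–2020 means computed transform-then-average (log
first, then mean — geometric-mean-like, appropriate for right-skewed GDP and
water series); average-then-transform is a switch since the two differ
materially (log₁₀ of the mean of {100, 1000, 10000} is ≈ 3.57 versus 3.0).
The P₂ regression always uses national (area = total) rates and all four
factors, with no year dummy.

Known limitation: the exclusion rule is selection on the outcome. When the
P₂ distribution sits close to the −0.05 cutoff (mean P₂ ≲ 0.1), the rule
truncates the noise distribution asymmetrically with respect to covariates,
and credible intervals for weakly-identified coefficients undercover the
generating values by several percentage points. The recovery tests therefore
use a mid-range P₂ regime (mean ≈ 0.5) where the rule is almost surely
inactive, isolating estimation quality from truncation; the truncation
behaviour itself is inherent to the procedure, not to this implementation.

## Synthetic data

The generator draws, per country, a correlated covariate vector on the
transformed scale — log₁₀ GDP per capita ~ N(3.7, 0.55²), urban population
rate ~ N(55, 22²) (clipped to [1, 100]), democracy index ~ N(5.5, 2²)
(clipped to [0, 10]), log₁₀ renewable water per capita ~ N(3.3, 0.7²), with
GDP–urbanization correlation 0.6, GDP–democracy 0.5, urbanization–democracy
0.35 — applies a 20-year drift (+0.20 log₁₀ GDP, +6 points urban, +0.2
democracy, −0.05 log₁₀ water per capita, the latter reflecting population
growth), and back-transforms to raw scale. These values were chosen once as
representative of cross-country panels of ~100–150 complete-case countries.

Access rates follow the generative model exactly: z-score the transformed
covariates within the panel, apply the true coefficients (drinking water
basic-or-higher: intercept 2.0, GDP 1.0, urban 0.3, democracy 0.1, year
dummy −0.5; sanitation: 1.7, 1.7, 0.3, 0.0, −0.54), add Normal(0, σ_obs)
noise on the rate scale with σ_obs = 0.05, *without clipping* by default so
recovery tests are exact-model tests (a clipped mode exists for robustness
studies). Renewable water is generated but has zero effect on access,
mirroring its failure to pass the screening stage. Ladder rows are emitted
consistently: `at_least_basic` is the basic-or-higher rate, `safely_managed`
a fixed 0.7 share of it, `basic` the remainder, so the cumulative-aggregation
policy and the ladder-consistency invariant are both exercised.

What the generator does *not* emulate: real country identities or income
distributions, survey measurement error structure, temporal autocorrelation
beyond the linear drift, area (urban/rural) heterogeneity, or
limited/unimproved/surface-water ladder levels. Passing recovery tests
therefore demonstrates correctness of the estimation machinery under the
model's own assumptions — not robustness to the ways real JMP data violate
them.

## Numerical choices

- Logistic evaluated in the stable two-branch form; finite for |η| ≤ 1e3.
- Log posterior keeps all density constants so independent term-by-term
  oracles match exactly (tested to 1e−10); σ ≤ 0 maps to −∞.
- z-scoring rejects constant columns (zero variance) rather than returning
  NaNs; dataset assembly rejects fewer than 10 complete rows, where the model
  is not identifiable in practice.
- R-hat returns the degenerate marker 1.0 (with a warning) when every split
  chain is constant; VIF reports `inf` at R² ≥ 1 − 1e−12.
- Equal-tailed credible intervals via pooled-draw quantiles (no
  interpolation subtleties matter at ≥ 4,000 draws).
- Rates arriving as percentages are divided by 100 exactly once, at read
  time, under an explicitly declared dialect — never sniffed.
- Per-stage MCMC seeds are derived from the run seed and the model's labels
  (CRC of service/quality/area/factors), so stages can run in any order with
  identical results.

## Problem sizes

Tests and the acceptance script run 20-replicate recovery studies at the
published panel scale (150 countries × 2 years; 140 countries for the
improvement regression) with 2 chains × 3,000 iterations; the full suite
completes in well under a minute on one CPU. These sizes give Monte Carlo
error comfortably below the assertion tolerances (coverage ≥ 17/20 per
coefficient, mean absolute bias < 0.05).
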