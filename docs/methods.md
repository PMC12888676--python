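# Methods

## Error model and scope

All calculators assume the classical measurement error model on the natural
log scale: an observed measurement is the person's true long-run mean
exposure plus additive, independent, homoscedastic, normally distributed
noise, with the noise independent of the true value and of the outcome
(non-differential). True exposures are normal across the population. The
two inputs everything else derives from are the between-person variance
σ²_B of true means and the within-person variance σ²_W of single
measurements. Averaging m measurements divides the error variance by m;
temporal autocorrelation between repeats is ignored (repeats are treated as
exchangeable draws). Multiplicative and Berkson error structures,
measurement error in the outcome or in covariates, confounding, and
non-normal exposure distributions are out of scope; the simulation engine
is written so such extensions slot into `simulate_replicate` without
touching the summaries.

## Parameters and defaults

| Parameter | Meaning | Units | Default |
|---|---|---|---|
| σ²_B, σ²_W | between/within-person variance of ln-exposure | ln-units² | — (study-specific) |
| m | measurements averaged per subject | count | 1 |
| σ²_y | marginal outcome variance | outcome units² | — |
| β | true or detectable slope | outcome units per ln-unit | — |
| α | two-sided Type I error | — | 0.01 linear, 0.05 logistic |
| power | target power | — | 0.90 |
| p₀ | marginal incidence of the binary outcome | — | — |
| n_reps | logistic simulation replicates | count | 2000 |

`CONFIRMATORY` (α = 0.01, power 0.90) and `EXPLORATORY` (α = 0.05, power
0.80) bundle the test-spec defaults for the two common planning postures;
the stricter pair is the default because these calculators exist to vet
studies that claim to confirm an association. 2,000 replicates put a
one-sided Monte-Carlo standard error of about 0.6 percentage points on a
power near 7%, which is tight enough to separate the design-relevant
alternatives (7% vs 90%) while keeping a full run under ten seconds.

## Conventions that needed pinning down

- **Required repeats are rounded up.** The reliability inversion returns a
  real number; the integer answer is its ceiling (minimum 1), because the
  question is "how many samples guarantee at least this validity". A
  1e-9 tolerance guards exact-integer solutions against float drift.
- **Sample sizes are rounded to the nearest integer** (half away from
  zero). Rounding n up instead would be defensible; nearest is used
  consistently, and `power_for_design` shows the resulting power deficit is
  at most ~1e-4 at realistic sizes.
- **The no-error sample size uses residual variance** σ²_y − β²σ²_B, not
  the marginal σ²_y: the slope test's noise is the outcome variation not
  explained by exposure. Normal quantiles are used rather than t (the
  difference is <0.5% at the sample sizes these designs produce).
- **Fractional m is accepted** by the validity and attenuation formulas so
  that the repeats solver and the validity coefficient are exact algebraic
  inverses; only the integer-facing solvers (`repeats_for_validity`'s
  second return, `repeats_for_max_bias`) round.
- **(ICC, variance) parameterization.** When a source reports a reliability
  and a single total variance, the total is treated as between-person (the
  optimistic, bias-minimizing reading) and σ²_W = σ²_B(1 − ICC)/ICC is
  derived. This is how the triclosan case-study components (0.0127, 0.0143)
  arise from the published totals (0.019, 0.0095).
- **Baseline incidence is marginal.** The logistic intercept is calibrated
  so the population-averaged incidence equals p₀, via 64-node Gauss–Hermite
  quadrature and Brent root-finding to |residual| < 1e-12 (the root is
  unique because the marginal incidence is strictly increasing in the
  intercept). Setting the intercept to logit(p₀) instead would make p₀ the
  incidence at the mean exposure; the numerical difference is second-order
  here but the convention must be fixed. The exposure mean is set to 0
  without loss of generality — location shifts are absorbed by the
  intercept.
- **The significance test is the two-sided Wald test** on the exposure
  slope, as reported by a standard maximum-likelihood logistic fit
  (statsmodels).
- **Degenerate replicates** (all-0/all-1 outcomes, separation, optimizer
  non-convergence) are excluded from both the power and bias summaries and
  counted in `n_excluded`; a warning is recorded when more than 10% of
  replicates are excluded, and a run with zero usable replicates raises.
  Percentiles use linear interpolation between order statistics.
- **Reproducibility.** One root seed spawns an independent child RNG stream
  per replicate (`numpy.random.SeedSequence`), so results are bit-identical
  for a given spec and seed regardless of execution order.
- **Degenerate inputs are rejected, not coerced**: σ²_B = 0 makes
  attenuation and the repeats inversion undefined (error), ICC or ρ at 0/1
  make the repeats formula diverge (error), and a β with β²σ²_B ≥ σ²_y
  implies non-positive residual variance (error).

## What the simulations emulate — and what they do not

The Monte-Carlo engine and the test-suite oracles generate exactly the
world the closed forms assume: normal true exposures, normal additive
errors, exchangeable repeats, a correctly specified single-exposure
regression. Passing tests therefore demonstrate internal consistency
(simulation agrees with formula) and correctness of the implementation,
not robustness of the design advice to skewed exposures, autocorrelated
repeats, model misspecification, or confounding — real data violate at
least some of these, usually in the direction of making the printed power
still optimistic.

Two consistency anchors are worth stating. First, for small slopes the
logistic simulator's median estimated OR recenters at `OR_true^λ` with λ
the linear attenuation factor — at the bisphenol case-study settings
(λ = 0.368, OR 1.14) this predicts a median bias of −7.9%, and the
simulator reproduces it. Second, simulating linear-regression studies at
the sample size the formula prescribes yields empirical rejection rates at
the target power within Monte-Carlo error.

## Numerical and test problem sizes

The formula-vs-simulation oracles use 10⁵ simulated persons (attenuation),
2,000 replicates of vectorized OLS (linear power), and 400–2,000 logistic
replicates at n between 200 and 2,758, sizes at which Monte-Carlo standard
errors are small enough for 2-SE acceptance bands while a full suite run
stays around twenty seconds. The bisection oracles for the inverse
relations run 200 iterations, far past 1e-6 relative agreement.

## Known limitations and deliberate discrepancies

- The within/between decomposition must be supplied; estimating it from
  pilot repeated-measures data (ANOVA estimators) is deliberately not
  included.
- One published narrative value is knowingly not reproduced: for the
  bisphenol components, a 10%-bias threshold is sometimes quoted as met at
  m ≥ 30, but the bias formula gives 10.26% at m = 30 and 9.96% at m = 31;
  `repeats_for_max_bias` follows the formula and returns 31.
- Published minimum-detectable-effect figures for the case-study cohorts
  (e.g. 0.42 at n = 1,379, m = 1) do not agree with any rearrangement of
  the sample-size formula implemented here; this package's `mde_for_n` is
  the exact inverse of its own verified sample-size calculation (0.466 for
  that design) and is cross-checked against a bisection oracle instead.
  Similarly, published triclosan sample sizes (≈122,000 at m = 1) differ by
  ~2% from the formula, although their ratios across m match 1/ρ²(m)
  exactly, suggesting a slightly different outcome-variance input; the
  package reports its own computed values.
- Whether the triclosan outcome "6" is a variance or a standard deviation
  is ambiguous in the sources; the fixtures store it as a variance.
- The cost-optimal allocation of n versus m under a budget
  (Armstrong-style efficiency) is not implemented.
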