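# Methods

## Model and test

Two treatment groups, one continuous covariate, straight-line regressions
with possibly unequal slopes:

    Y_gj = β0g + β1g X_gj + ε_gj,   ε_gj ~ iid N(0, σ²),   g = 1, 2.

Equivalently, with a group indicator M (1 for group 1, 0 for group 2), the
single interactive regression

    Y = β02 + M β0D + X β12 + M X β1D + ε,   β1D = β11 − β12.

The two parameterizations are algebraically identical: the separate-fits
slope difference, pooled residual sum of squares and degrees of freedom all
coincide with the dummy-variable fit (asserted by a regression test against
`numpy.linalg.lstsq` on the full design matrix).

The heterogeneity-of-slopes statistic is

    T = β̂1D / √{σ̂² (1/SSX1 + 1/SSX2)},   σ̂² = SSE/ν,   ν = N − 4,

with SSE pooled from the *two separate* within-group fits — never from a
common-slope model, whose residual variance would be inflated under the
alternative. Under H0: β11 = β12, T ~ t(ν); the test is two-sided, rejecting
when |T| > t_{ν,α/2}. One-sided testing is out of scope. p-values are
reported as 2·(1 − F_{t(ν)}(|T|)); the rejection flag is decided on |T|
against the critical value, not on the rounded p.

## Unconditional power with random covariates

Conditional on the covariate sums of squares, T ~ t(ν, Δ) with
Δ = δ / √(1/SSX1 + 1/SSX2) and δ = β1D/σ. At the planning stage SSX1 and
SSX2 are random; with independent normal covariates
X_g ~ N(θ_g, τ_g²), the scaled sums of squares K_g = SSX_g/τ_g² are
independent χ²(κ_g), κ_g = N_g − 1. Transforming to K = K1 + K2 ~ χ²(κ) and
B = K1/K ~ Beta(κ1/2, κ2/2), independent, gives the two-stage law used by
the exact power:

    Ψ_KB = E_K E_B [ P{ |t(ν, Δ_KB)| > t_{ν,α/2} } ],
    Δ_KB = δ √{ K / [ 1/(B τ1²) + 1/((1−B) τ2²) ] }.

The approximate power Ψ_A substitutes E[SSX_g] = κ_g τ_g², yielding a single
noncentral-t evaluation with
Δ_A = δ √{ κ / [ 1/(b1 τ1²) + 1/(b2 τ2²) ] }, where b1 = κ1/κ and
b2 = κ2/κ (the weights sum to one; anything else would break the
expected-sum-of-squares substitution for unbalanced designs). The
Dupont–Plummer power Ψ_DP uses the same noncentrality built from the
allocation fractions p_g = N_g/N but treats T as a *shifted* central t,
t(ν) + Δ_DP — computationally convenient, but a shifted t is not a
noncentral t, and the formula systematically overstates power at small N.

Three structural facts, each enforced by tests: all three powers equal α at
δ = 0; all are invariant under δ → −δ and under exchanging (n1, τ1²) with
(n2, τ2²); none depends on the covariate means θ_g or the intercepts β0g,
which are accepted and stored but never consulted. Both rejection tails are
always evaluated, even when the lower tail is numerically negligible.

## Numerical evaluation of Ψ_KB

Each mixing variable is mapped to probability space through its inverse CDF
and the double integral is evaluated by tensor-product Gauss–Legendre
quadrature on [ε, 1 − ε]², with the conditional rejection probability
computed from `scipy.stats.nct` (never by simulation). Defaults:
256 nodes per dimension, ε = 1e-8 (truncation error ≤ 2ε per dimension).

The integrand is smooth and bounded in the interior, but the inverse-CDF map
has unbounded derivative at the interval ends, so node convergence is
algebraic rather than spectral. 64 nodes leave a node-doubling change of
about 4e-6; 256 nodes bring it below 6e-7 on every reference design at
roughly 0.18 s per evaluation on one core, which is the accuracy/cost point
chosen for the default. The quadrature settings actually used are recorded
in `PowerResult.numeric_detail`, and the result is bit-for-bit reproducible
for fixed settings. An independent cross-check samples (K, B) directly and
averages the conditional rejection probability; the quadrature agrees with
this Monte Carlo mixture estimate well within its sampling error.

## Sample-size determination

`find_sample_size` returns the smallest n1 (n2 = ⌈r·n1⌉ at allocation ratio
r) whose power reaches the target, by doubling to bracket and then bisecting
— valid because power is monotone in n1 at fixed ratio, a property the test
suite checks on grids. A linear scan over n1 = 2, 3, … serves as the test
oracle. Rounding n2 upward means a fractional ratio never under-allocates
the second group. Minimality is defined on exact floating-point power, not
the 4-decimal display. Requests with target power ≤ α are rejected as
degenerate, and the search errors out above a configurable cap
(default n1 ≤ 10⁶) rather than looping. Because sizes are integers, achieved
power slightly exceeds the target; the approximate methods, which overstate
power, return sizes no larger than the exact method's (also asserted).

## Effect-size estimation

The first moment of t(ν, Δ) is E[T] = √(ν/2) Γ((ν−1)/2) Δ / Γ(ν/2), so the
plug-in estimate β̂1D/σ̂ is biased upward. The package reports

    δ̂_UE = [Γ(ν/2) / (√(ν/2) Γ((ν−1)/2))] · β̂1D/σ̂,

unbiased for δ conditionally on the covariates and hence unconditionally.
The gamma ratio is evaluated via log-gamma differences, so it stays finite
for arbitrarily large ν; it requires ν ≥ 2. A 10⁵-replicate simulation at
δ = 0.5 recovers the true effect within Monte Carlo error.

## Monte Carlo engine

`simulate_power` replicates the full pipeline — draw covariates, build
responses Y = β0g + β1g X + ε, run the t test — and reports the rejection
fraction with its binomial standard error √{p(1−p)/R}. Default 10,000
replicates. One `numpy.random.Generator` stream per run, seeded once;
replicates are processed in fixed chunks of 4096, drawing all group-1
covariates, then group-2 covariates, then the errors. Location parameters
(covariate means, intercepts) are added after variate generation, so
changing them provably leaves the rejection sequence identical for the same
seed — the simulation-level counterpart of the power functions' location
invariance.

Covariate generators cover normal, beta, exponential, gamma, laplace and
uniform families. Each generator is rescaled multiplicatively so its
closed-form variance equals the requested τ² exactly: Beta(2, 5) is divided
by c = √(Var_raw/τ²); Exponential(scale √τ²), Gamma(2, √(τ²/2)) and
Laplace(rate √(2/τ²)) hit the target by parameter choice (scale factor 1);
Uniform(−1/2, 1/2) is stretched to endpoints ±√(3τ²). A Laplace parameter is
interpreted as a *rate* λ with Var = 2/λ². Non-normal families keep their
natural locations — power is location-invariant, so centering is pointless.

What the generator does and does not emulate: it reproduces the design
conditions of the validation studies (iid covariates within group, normal
homoscedastic errors, exact target variances). It does not model covariate
measurement error, within-group heteroscedasticity, non-normal response
errors, correlated covariates, or missing data — so passing simulation
checks say nothing about those violations. The non-normal families probe
only one assumption, the covariate's distributional shape; under heavy
tails (exponential) the chi-square mixture misrepresents the SSX law and
Ψ_KB overestimates true power, a deficiency the test suite asserts rather
than hides.

## Defaults and conventions

| Parameter | Default | Why |
|---|---|---|
| α | 0.05, two-sided | Standard planning level; one-sided out of scope |
| target power | user-supplied, must exceed α | below α the search is degenerate |
| allocation ratio r | 1 | balanced designs dominate practice |
| quadrature | 256 × 256 nodes, ε = 1e-8 | node-doubling change < 1e-6 |
| replicates | 10,000 | power SE ≈ 0.004 near p = 0.8 |
| ν | always N − 4 | two intercepts + two slopes, never configurable |

Validation-study problem sizes: the bundled acceptance checks run the
analytic columns in full (all ten normal-covariate designs) and the
simulation comparisons at 2,000 replicates with 3-standard-error tolerances;
the distribution-level checks (null t(ν) calibration, estimator recovery)
use 50,000–100,000 replicates through the vectorized kernel.

## Known limitations

- Exactly two groups and one covariate; no multi-group or multi-covariate
  extension, no heteroscedastic error variances.
- Ψ_KB's exactness is itself conditional on normal covariates; for
  non-normal covariates it is an approximation whose error grows with
  skewness/kurtosis (largest for exponential among the bundled families).
- No confidence intervals for β1D or δ, and no follow-up procedures
  (Johnson–Neyman style regions) after a significant interaction.
- The search assumes power is monotone in n1 at a fixed ratio; this holds
  for all three formulas here but is asserted on grids, not proved in code.
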