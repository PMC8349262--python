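# Methods

## Model

Strength `X ~ Ku(α, β₁)` and stress `Y ~ Ku(α, β₂)` are independent
Kumaraswamy variables on (0, 1) with density `αβ x^{α−1}(1−x^α)^{β−1}` and
cdf `F(x) = 1 − (1−x^α)^β`.  The common first shape α is a structural
assumption: it is what makes both the conditional reliability and the
profile likelihood tractable.  The estimand is

    R^{|a,b} = P(X > Y | X > a, Y > b),

with known thresholds `a, b ∈ [0, 1)` (values ≥ 1 would condition on a
null event and are rejected).  Writing `Q = (1−b^α)/(1−a^α)`, the closed
form is `β₂/(β₁+β₂)` for `a=b`, `β₂/(β₁+β₂)·Q^{β₁}` for `a<b`, and
`1 − β₁/(β₁+β₂)·Q^{−β₂}` for `a>b`.  At `a=b` the thresholds cancel and
the unconditional `P(X>Y)` is recovered; both unequal-threshold branches
are continuous in that limit.  Branch dispatch uses exact floating
equality of `a` and `b`; the continuity makes the branch choice
numerically immaterial near the boundary (verified to 1e−6 at
|a−b| = 1e−8).

A quadrature evaluator integrates the defining tail integrals
(`∫ (1−F_X) dF_Y` type) over `[max(a,b), 1]` — the integrands vanish
beyond 1, so the integration stops there — and serves as an independent
oracle for the closed form (agreement to 1e−8 everywhere tested).

## Maximum likelihood

With samples of sizes n and m, the log-likelihood depends on the data only
through `lx = Σ ln xᵢ`, `ly`, `lxx(α) = Σ ln(1−xᵢ^α)`, `lyy(α)`.  Given α
the betas maximise in closed form, `β̂₁(α) = −n/lxx(α)`,
`β̂₂(α) = −m/lyy(α)`, so the fit reduces to the scalar root of the profile
score in α (the envelope theorem makes the profile derivative equal the
α-partial at the profiled betas; the test suite checks this against finite
differences of the profile log-likelihood).  The score tends to +∞ as
α→0⁺ and is eventually negative, so the root is found by Brent's method
after geometric bracket expansion from [0.1, 10] (floor 1e−6, ceiling
1e6).  If expansion ever produced several sign changes, the root with the
highest profiled log-likelihood would win — the MLE is defined by the
maximum, not by the root.

Powers are evaluated in log space (`x^α = exp(α ln x)`,
`ln(1−x^α) = log1p(−exp(α ln x))`) to survive large α with small x.
Observations equal to 0 or 1 are rejected, not clipped: the likelihood is
undefined there and clipping would bias the betas.  Sample sizes below 2
per arm are rejected because the downstream variances are degenerate.

## Asymptotic variance and Wald intervals

The observed information is the analytic negated Hessian; it is validated
entry-wise against finite differences.  Its expectation uses the Beta(1,β)
law of `t = x^α` and the moment integrals
`∫ t^{x−1}(1−t)^{y−1} ln t dt = B(x,y)[ψ(x)−ψ(x+y)]` (and the `ln²t`
analogue with trigamma terms).  The resulting closed forms involve
`B(2, β−2)` in the α-curvature and `B(2, β−1)` in the mixed entries, hence
exist only for β > 2 resp. β > 1; below those the code evaluates the
(always finite) expectation integrals by adaptive quadrature instead.
ψ′(2) is taken from the polygamma function (= π²/6 − 1).

The delta-method variance of the plug-in estimator is the quadratic form
`ġ Σ ġᵀ` with `Σ = J⁻¹` (expected information at the plug-in θ̂, matching
the J-based asymptotic covariance; 3×3 inversion by explicit cofactors)
and `ġ` the analytic gradient of the closed-form reliability.  A fully
expanded scalar variance — through the aggregates `A = α²J₁₁`,
`C = α²J₁₃²/J₃₃`, `D = α²J₁₂²/J₂₂` and the beta/digamma constants —
is computed alongside as a cross-check whenever both betas exceed 2; the
two routes agree to 1e−10 on the tested grid, and the quadratic form is
authoritative.  The equal-threshold case has ∂R/∂α ≡ 0, so α's
uncertainty then contributes nothing to the variance.

Wald intervals are `R̂ ∓ z·σ̂` with the normal quantile at full double
precision.  Intervals are **not** clipped to [0, 1] by default (the
published bootstrap tables print a negative lower bound, so the original
study did not clip either); clipping is available as an option.

## Bayesian estimation

Independent gamma (shape, rate) priors on (α, β₁, β₂); defaults
`aᵢ = bᵢ = 0.1` (proper, prior mean 1, variance 10) keep desk-scale
posteriors likelihood-dominated while remaining proper.  Given α, the
betas have exact gamma full conditionals
`β₁ | · ~ Gamma(a₂+n, b₂ − lxx(α))` (the rate is positive because
lxx < 0), so only α needs Metropolis–Hastings: a Gaussian random walk on
ln α with the Jacobian term in the acceptance ratio, optionally tuned by
Robbins–Monro toward 0.44 acceptance during burn-in only (the post-burn-in
chain targets the exact posterior).  The α-conditional is derived directly
from the joint posterior; a literal reading of the published conditional
would double-count the α-likelihood terms.  Defaults: 6000 sweeps, 1000
burn-in, single chain started at the MLE; acceptance rate, lag-1
autocorrelation and a crude effective sample size are always reported.
The point estimator is the posterior mean (squared-error loss); intervals
are equal-tailed quantiles of the reliability draws.

Validation: conditional moments against the analytic gamma law, a
KS comparison of a long α-chain against the grid-normalised exact
conditional, and a successive-conditional (prior → data → one posterior
sweep) chain whose α margin must preserve the prior mean.

## Bootstrap

Parametric percentile bootstrap exactly as the three-step recipe: refit
the full triple on each of N sample pairs regenerated from the fitted
laws, then take equal-tailed empirical quantiles (numpy's linear
interpolation between closest ranks, held fixed).  Default N = 1000 —
percentile stability at the 95% level needs about that many.  An economy
mode keeps α̂ fixed and refits only the betas.  Failed refits are dropped
and counted; more than 1% failures raises.

## Simulation harness

A study cell draws `reps` independent sample pairs, estimates per
replicate, and reports mean estimate, bias (against the closed-form true
value), MSE, coverage probability of the nominal-level interval (again
against the true value), mean interval length, and the number of failed
replicates (dropped, never imputed; >5% failures aborts the cell).
Replicate i is seeded from `SeedSequence((seed, i))`, so results are
independent of execution order and the first k replicates never change
when `reps` grows.  The MLE path is vectorised across replicates
(matrix-valued profile score, bracket expansion plus 70 bisection steps,
batched 3×3 covariance solves), which puts a 5000-replication cell at
n = m = 100 around one second; the scalar and batch fitters are asserted
to agree row by row.  Bayes and bootstrap columns default to reduced
settings inside the study (3000/500 MCMC sweeps, N = 500) and are
configurable upward.

## Fixture generation and what the tests show

All test data are i.i.d. inversion samples from the two study scenarios
(α=5, β₁=3.5, β₂=3.25 and α=1.25, β₁=7, β₂=4.2; thresholds a=0.1, b=0.2)
— exactly the conditions of the published study, which is itself fully
synthetic.  What passing tests do **not** show: behaviour under model
misspecification (non-Kumaraswamy data, unequal first shapes), dependence
between stress and strength, or censoring — all outside this model.

Problem sizes used in the checked claims: 5000 Monte Carlo replications
for the table cells; 2000 replications for the information-expectation and
delta-variance calibration checks; 500 outer replications (N = 1000 inner)
for bootstrap coverage; 40 datasets at n = m = 200 for the posterior-bias
check.

## Known discrepancies with the published tables

- The published MSE column is internally inconsistent at several sample
  sizes: e.g. at (100,100), scenario 1, the printed mean interval length
  0.1376 implies an average standard error of 0.0351 (variance ≈ 0.00123),
  and the delta-method variance at the truth is 0.001247, yet the printed
  MSE is 0.0010.  This reproduction obtains MSE ≈ 0.0013, consistent with
  both of the former; the mean-estimate, coverage and length columns match
  the published table throughout.  The published column is also
  non-monotone in n (0.0028 at (35,35) vs 0.0030 at (50,50)).
- The published (5,15) unbalanced row (mean 0.4040, coverage 0.50) is far
  from both this reproduction (≈0.46, ≈0.87) and the asymptotic theory.
- The Bayesian and bootstrap tables cannot be reproduced numerically: the
  study does not state its prior hyperparameters or bootstrap N (and one
  Bayesian row has transposed estimate/bias entries).  Those methods are
  validated by calibration properties instead (conditional-moment checks,
  posterior bias at large n, bootstrap coverage near nominal).
- One printed trigamma constant (ψ′(2) as "π/6 − 1") is a typo for
  π²/6 − 1; the printed expanded-variance cross terms are garbled in
  extraction and were re-derived from the quadratic form.
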