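# Methods

This note documents the statistical models, the synthetic-data
generator, and the numerical and design choices behind `selfreg`.

## The wait-time model and the rank-normalized delay score (RND)

Preschool delay-of-gratification experiments record how long a child
waits for a larger reward, censored at a limit *c* (900 s by default),
under one of *G* experimental conditions of very different difficulty
and very different size (3 to 165 children per condition in the design
emulated here).  The latent log wait time is modelled as

    y*_gi = α + β₁ age_gi + β₂ male_gi + η_g + ε_gi,
    η_g ~ N(0, σ_η²),   ε_gi ~ N(0, σ_ε²),

with observed wait min(exp(y*), c).  The condition effect is a random
effect precisely because several conditions are tiny: fixed effects
would be extremely noisy there, while the random-effects posterior
shrinks small conditions toward the grand mean.

**Estimation.**  The marginal likelihood integrates η_g out of each
condition's contribution; censored records contribute the upper-tail
probability Φ((μ + η − ln c)/σ_ε) and uncensored records the normal
density at ln(wait).  The integral is evaluated by *adaptive*
Gauss–Hermite quadrature (21 nodes by default): per condition, a
vectorized Newton iteration finds the mode of the log-concave
integrand, the nodes are centred and scaled by the mode and curvature,
and the weighted log-sum-exp gives the per-condition log-likelihood.
A grid-integration cross-check of the empirical-Bayes posterior means
is part of the test suite.  Optimization is L-BFGS-B on
(α, β₁, β₂, log σ_η, log σ_ε) from a moment-based start plus two
perturbed restarts; an unsuccessful line search at an interior optimum
is resolved by a Nelder–Mead polish and accepted only if the gradient
is negligible.  Standard errors come from the numerically
differentiated observed information in the natural parameterization.

Validation at the default design (543 children, 21 conditions,
generating parameters α=2.289, β₁=0.081, β₂=−0.673, σ_η=0.786,
σ_ε=2.469): across 50 replicate fits every parameter is recovered
without visible bias and the replicate SDs match the model-based
standard errors; 92–94% of estimates fall within ±2 SE of the truth.

**RND.**  Each child's expected log wait is the fixed part plus the
empirical-Bayes posterior mean of their condition effect, with the
parameter estimates treated as known.  For censored children the
actual log wait is replaced by the Monte-Carlo conditional expectation
E[y* | y* ≥ ln c, age, sex, condition] (10,000 truncated-normal draws
by default, sampled by inverse CDF through the log-CDF so the far tail
is stable; the closed inverse-Mills form is the test oracle).  By
default the condition effect enters imputation as its point estimate;
`integrate_eta=True` instead redraws it from a normal approximation to
its posterior on every draw — at the default design the two differ by
far less than the imputation Monte-Carlo error.  The deviations
(actual-or-imputed minus expected log wait) are rank-normalized into
RND within the estimation sample.

Waits recorded as 0 s are floored at 1 s before logging (ln 0 is
undefined; 1 s is below any behaviourally meaningful wait).  Repeat
records for a participant are dropped keeping the first, since only
the first exposure to the task is comparable across children.

## Rank-based inverse normal transformation

All analysis variables are mapped to a standard-normal scale: average
ranks r within the non-missing sample, probability (r − 0.5)/n, then
the standard-normal quantile.  Blom's (r − 3/8)/(n + 1/4) is available
as a config alternative; at n ≈ 110 the two differ by < 0.01
everywhere.  The quantile is evaluated on the lower tail and mirrored,
making the map exactly antisymmetric — reversing a tie-free variable
flips the scores bit for bit, which the index code relies on for its
degenerate-input detection.  Vectors that are entirely missing or
entirely tied raise a degenerate-input error rather than silently
producing a constant score.

## Indices

* CCQ batteries at ages 17/27/37 are scored per subscale (sign-keyed
  item mean, requiring at least half the items; rank-normalized), then
  averaged over the six subscales (at least 3 observed) and
  rank-normalized (RNCCQ per age).
* RNSRI is the rank-normalized equal-weighted mean of RND and the
  three RNCCQ scores, requiring at least 3 of the 4 components; the
  threshold is configurable, and complete-case behaviour is obtained
  with `min_present=4`.  The data do not identify the original study's
  exact partial-missingness rule, so both are exposed.
* Outcome composites (credit-card misuse, financial health,
  forward-looking behaviors, the capital-formation index) use
  `equal_weight_index`: rank-normalize components, average where at
  least `min_present` are observed, re-rank-normalize.  Component
  weights inside the multi-component outcomes are equal — the natural
  reading absent any published weighting.
* High-interest debt is Σ amount × max(rate − 6%, 0) over debt
  categories with bucket-midpoint rates; it and credit-card misuse are
  reverse-scaled before rank-normalization so larger always means
  better.

## Inference battery

* **Per-outcome OLS** of each rank-normalized outcome on the predictor
  plus sex (savings rate also controls for permanent income);
  conventional SEs, two-sided p from t with N − k df.
* **FDR** control by Benjamini–Hochberg step-up at q = 0.1, applied
  separately per predictor (backed by `statsmodels.multipletests`,
  cross-checked against a brute-force step-up oracle).
* **Joint permutation Wald test.**  The observed statistic is
  W = b'V⁻¹b over the 11 predictor coefficients.  The cross-equation
  covariance V is assembled from participant-level score contributions
  ψ_ij = a_ij e_ij over the union of each outcome's complete cases
  ("shared" mode), which respects the differing per-outcome Ns; a
  common-complete-case mode is also provided, and the two coincide on
  complete data.  The null distribution permutes the rows of the
  outcome matrix jointly (preserving cross-outcome dependence under
  the null of no association with the predictor); per-outcome
  independent permutation is available as an option.  The empirical
  p-value uses the add-one rule (1 + #{W_perm ≥ W_obs})/(B + 1), upper
  tail, so p ≥ 1/(B+1) always.  Calibration: across 500 null
  replicates (n = 113, 11 outcomes, B = 199) the rejection rate at
  nominal 0.05 lies inside [0.03, 0.07].
* **Bayesian shrinkage**: conjugate normal-normal posterior per
  coefficient; priors default to mean 0.15, SD 0.2 for the composite
  index and mean 0.05, SD 0.2 for the preschool score (the prior SD
  for the latter is a package default on the same scale as the index
  prior, configurable and logged in every manifest).
* **Averaging**: unweighted mean of coefficients, signs as-is for the
  main batteries (reverse-scaling already encodes direction),
  absolute-value adjustment for per-item analyses; SE by
  participant-level bootstrap re-running all regressions.
* **Power check**: replicate cohorts with loadings rescaled so the
  battery mean correlation sits at the prior mean; reports the
  fraction of replicates with joint-Wald p < 0.05 and with ≥ 1 FDR
  discovery.

## Synthetic cohort generator

One latent self-regulation factor per child ties everything together:

* wait-time error: ε = σ_ε(√w·latent + √(1−w)·noise), where w
  (`latent_loading_wait`, default 0.011) is the share of individual
  log-wait variance carried by the factor;
* CCQ items: loading 0.4 on the factor, unit total variance, every
  5th item reverse-keyed; 23/31/31 items at ages 17/27/37;
* outcomes: correlation-scale loading (default 0.21) on the factor,
  the two debt outcomes generated in the undesirable direction.

Ages are truncated-normal (mean 52.1 months, SD 5.7, range 24–72);
sex is Bernoulli(0.48); condition sizes default to a fixed 21-way
allocation of 543 children spanning 3–165.  A random survey subsample
(113) carries items and outcomes; per-outcome missingness is MCAR with
rates chosen to land analysis Ns in the observed 103–113 range, and a
10% per-age CCQ wave nonresponse makes a few participants miss the
composite index under the 3-of-4 rule.  Roughly 6 of 21 conditions are
flagged "diagnostic" so that ≈30% of participants sit in one; the
optional `diagnostic_loading_boost` inflates the wait-time latent
share only there, for mechanism experiments.  A single seed fans out
into per-component substreams, so cohorts are byte-identical given a
spec.

The default loadings are the output of `calibrate_effect_sizes`
targeting mean battery correlations of 0.19 (index) and 0.02
(preschool score): the calibrator iteratively rescales the outcome
loading and the wait latent share, measuring candidates by replicate
simulation with the wait model held at the generating truth, and
verifies the final spec on ≥200 fresh replicates to within ±0.02.
Full-pipeline recovery — re-estimating the wait model on every
replicate — reproduces the targets within ±0.03 over 200 replicates.

**What the generator does not emulate**: the real survey instrument,
recruitment and attrition, non-random survey selection (the real
survey sample skews female; ours is a random subsample), non-normal
raw outcome scales (rank-normalization makes the analysis invariant to
them, which is exactly why a normal latent scale suffices), item-level
factor structure beyond a single factor, and any
missing-not-at-random mechanism.  Passing tests therefore demonstrate
that the *pipeline* is correct and well calibrated under the study's
design, not that the substantive findings generalize.

## Numerical choices and degenerate inputs

* Quadrature nodes: 21 (configurable); the mode-finding Newton clips
  steps at ±10 and clamps the mathematically positive censored-record
  curvature term against floating-point cancellation in the far tail.
* Optimizer tolerances: ftol 1e−12, gtol 1e−7; σ parameters bounded
  away from 0 on the log scale.
* All-censored data has no interior optimum and raises immediately;
  a single condition leaves σ_η unidentified (fit a plain censored
  regression with `fix_sigma_eta=0.0` instead).
* Degenerate covariance in the joint test, empty p-value lists,
  all-missing components, and infeasible calibration targets raise
  typed errors with diagnostics rather than returning numbers.

## Validation problem sizes

Simulation-based checks in the test suite use the study's design sizes
(543 children, 21 conditions, 113 surveyed) with replicate counts of
50 (parameter recovery), 500 (joint-test size, B = 199), and 200
(full-pipeline effect-size recovery); smaller replicate counts appear
only in auxiliary monotonicity checks.
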