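# Methods

## The model family

Survey measurements of stigmatised or illegal behaviours (drug use,
risky sexual behaviour, under-reported income) are typically ordinal —
"not at all" up to "daily" — and heavily massed at zero.  The package
models an observed ordinal outcome y ∈ {0, …, J} as the product of three
latent Gaussian processes:

    r* = x_r'β_r + ε_r          participation       r = 1{r* > 0}
    m* = x_m'β_m + ε_m          truthful reporting  m = 1{m* > 0}
    ỹ* = x_y'β_y + ε_y          consumption         ỹ = j  ⇔  μ_{j-1} < ỹ* ≤ μ_j

with the observability rule y = r·m·ỹ, boundary normalisations μ_0 = 0,
μ_J = +∞, and unit error variances (probit scale).  An observed zero can
therefore come from a nonparticipant (r = 0), a participating
*misreporter* (r = 1, m = 0), or a truthful participant who consumed
nothing in the reference window (r = 1, m = 1, ỹ = 0): the zero cell is
"double-inflated".  Setting the misreporting hurdle to certainty
recovers the single-hurdle zero-inflated ordered probit (ZIOP); setting
both hurdles to certainty recovers the ordered probit (OP).  A
generalized ordered probit (GOP) comparator absorbs reporting behaviour
instead through covariate-dependent thresholds.

In the correlated variants (ZIOPC, DZIOPC) the errors are jointly normal
with correlation matrix Ω₃ (entries ρ_rm, ρ_ry, ρ_my), and the category
probabilities become bivariate/trivariate normal rectangle
probabilities, e.g.

    Pr(y=0|x) = Pr(r*≤0) + Pr(r*>0, m*≤0) + Pr(r*>0, m*>0, ỹ*≤0).

Every formula in the package is derived from a single signed-region
primitive P(s_k ε_k ≤ a_k, k ∈ region) with correlations s_k s_l ρ_kl,
equivalently from rectangle probabilities of Ω₃ — one audited code path,
cross-checked against brute-force Monte-Carlo region counts in the test
suite.  A joint test of Ω₃ = I₃ (likelihood ratio, 3 degrees of freedom,
statistic clipped at zero) compares the correlated model against its
independent-errors null.

### Assumptions worth stating

* Misreporters state *zero*, not a reduced positive amount; over-
  reporting is not modelled.
* The three decisions are simultaneous draws from one trivariate normal;
  there is no dynamic or panel structure.
* Identification of the misreporting equation leans on exclusion
  restrictions: covariates that shift reporting behaviour (survey mode,
  interviewer presence, distrust) but not participation or consumption.
  The package warns when x_r and x_m contain no mutually exclusive
  columns.  Our own recovery experiments (below) show that a strong,
  preferably continuous, misreporting instrument is not a nicety: with
  weak instruments the likelihood develops a flat ridge along which
  nonparticipation and misreporting trade off, and the MLE of the
  misreporting level becomes erratic even at n = 20,000.

## Probability engine

* **Univariate/bivariate.**  Φ via `scipy.special.ndtr`; Φ₂ via an
  in-package vectorised port of Genz's Gauss–Legendre algorithm
  (6/12/20 nodes by |ρ|, separate near-|ρ|=1 expansion), absolute error
  at machine precision, validated against `scipy.stats
  .multivariate_normal` on random instances.
* **Trivariate, deterministic.**  Rectangle probabilities with two
  lower-bounded dimensions and one band are computed as a composite
  Gauss–Legendre integral over the conditioning variable t of
  φ(t)·Φ₂(conditional orthant): panels at most 2.5 wide with 16 nodes
  each on the range truncated at |t| ≤ 8.5.  Worst-case absolute error
  is ~1e-14 over |ρ| ≤ 0.97, so category probabilities sum to one to
  machine precision.  A cheaper single-panel variant (~1e-6 worst case)
  backs finite-difference derivative work.  The public trivariate CDF
  also offers adaptive quadrature (`scipy.integrate.quad`) and reduces
  exactly to Φ₂ when a limit is infinite.
* **Trivariate, simulated (GHK).**  Recursive conditioning through the
  Cholesky factor of Ω₃ with inverse-CDF sampling of each truncated
  conditional.  Draws are scrambled Halton points (bases 2 and 3) with
  antithetic pairing — "500 draws" means 250 points plus complements —
  generated once per fit and reused at every parameter value (common
  random numbers), making the simulated likelihood a smooth
  deterministic function of the parameters.  At ρ = 0 the GHK
  probabilities are exact, which matters for the independence test's
  null behaviour.  Kernels are numba-compiled; the recursion is split
  into three stages so that likelihood evaluations perturbing only
  consumption-side parameters reuse the cached truncated draws of the
  first two dimensions (finite-difference gradients cost roughly a third
  of the naive price).

## Estimation

Maximum (simulated) likelihood by BFGS (`scipy.optimize.minimize`) on an
unconstrained parameterization:

* thresholds μ_1 = exp(c_1), μ_j = μ_{j-1} + exp(c_j);
* GOP row thresholds μ_j(z) = Σ_{k≤j} exp(c_k + z'γ_k) — ordered for
  every z by construction;
* correlations through tanh-transformed partial correlations in the
  fixed elimination order (ρ_rm, ρ_ry, ρ_my·r), each bounded at 0.99,
  which guarantees a positive-definite Ω₃ for any real input.  Fits
  flag correlations within 0.95 of the bound: ρ_ry and ρ_my are only
  weakly identified (the reporting and consumption latents are never
  observed separately).

The objective is the per-observation mean log-likelihood (probabilities
floored at 1e-300 before logging); gradients are central finite
differences with step 1e-5·(1+|θ_k|).  Convergence is declared when the
sup-norm of the mean score is below `tol` (default 1e-4, a scale at
which parameter error is well below one standard error at the
experiment sizes used here).  A fit never reports a point worse than its
starting value.

Warm starts are staged: a probit of 1{y>0} on x_r (statsmodels) for
β_r; a fast full-sample ordered-probit ML fit for (β_y, μ) — a fit on
positive rows alone cannot identify the zero-consumption boundary — and
β_m = 0 with intercept 1 (high prior truthful-reporting probability);
correlations start at zero.  DZIOPC fits additionally warm-start from
the DZIOP optimum and pre-solve at 64 GHK draws before the final
500-draw stage.

**Covariance.**  Robust "sandwich" H⁻¹(Σᵢ gᵢgᵢ')H⁻¹ and inverse-Hessian
covariances from finite-difference per-row scores and Hessian, mapped to
the reported parameterization through the numerical Jacobian of the
back-transform.  For DZIOPC both are evaluated on the deterministic
quadrature likelihood at the GHK optimum: second differences of an
already-approximate simulated objective would stack discretisation on
simulation error, and the quadrature path is both cheaper and exact.
Singular Hessians raise an error naming the flat directions.

## Partial effects and zero attribution

Partial effects are numerical: central differences for continuous
covariates, discrete 0→1 changes for binaries (switchable to
derivatives), evaluated at sample means of all design columns (each
squared term is its own regressor) or averaged over rows.  A covariate
entering several equations gets its total effect; the three zero-source
effects sum to the Pr(y=0) effect and the effects across all categories
sum to zero, both by construction (checked to 1e-8).  Standard errors
are delta-method with numerical Jacobians over the unconstrained
parameters and the sandwich covariance.

Prior zero decomposition: sample averages of the three per-row zero
components; their sum is the average predicted zero probability.
Posterior shares condition on an observed zero: the components
normalised by their sum, averaged over the y=0 rows — the model's answer
to "which fraction of the zeros are nonparticipants / misreporters /
infrequent consumers?".  Both variants' components are supported
(independent products, or the Φ₂/Φ₃ terms under correlation).

## Synthetic data

The generator draws covariates (independent Bernoulli and Gaussian
columns plus centred squares), then (ε_r, ε_m, ε_y) through the Cholesky
factor of Ω₃ from one seeded stream in fixed order, and applies the
threshold map and observability rule exactly.  Latent records (r*, m*,
ỹ*, r, m, ỹ) are emitted so posterior attributions can be compared with
realized ground truth.

`cannabis_preset` condenses the motivating application — a national
household drug survey with four ordered use categories and ~89% zeros —
to ten covariates with literature-typical coefficients (male 0.130 /
0.283 / 0.431 across the three equations; age −0.749 with a quadratic
consumption profile 1.609/−0.700; peer exposure 1.560; log-price 0.420;
thresholds 0.819, 1.568; under correlation ρ_rm = −0.591, ρ_ry = 0.038,
ρ_my = 0.280).  Intercepts were tuned once, by simulation at n = 60,000,
to the application's observable moments: ~90% observed zeros,
participation ~0.18, and roughly a fifth of participants misreporting.
`condensed_preset` (13 parameters; 16 with correlations) is the
recovery benchmark, with deliberately strong instruments — a binary
peer-exposure shifter in participation and a binary survey-mode plus a
*continuous* distrust score in misreporting — because recovery of the
misreporting level demonstrably requires them.  `independence_test_
preset` is a 9-parameter design with a moderate zero share used for the
null-distribution study of the independence test.

What the generator does **not** emulate: survey weights and sampling
design, covariate dependence (columns are independent; a correlation
hook would be needed for, say, age-education dependence), price-series
panel structure, item nonresponse.  Passing tests therefore certify the
estimator under a correctly-specified, independent-covariate DGP — not
robustness to real survey complications.

## Validation experiments (the package's standing evidence)

Sizes were chosen as the package's standard validation scale:

* probability-engine oracle: 25 random trivariate rectangles; GHK (500
  draws) vs composite quadrature vs 10⁷-draw Monte Carlo, all pairwise
  within 3 combined SEs;
* normalization: 1,000 random parameter/covariate draws across all six
  variants; worst row-sum deviation ~1e-15 (quadrature) and exact at the
  tested GHK settings;
* nesting: frozen-correlation DZIOPC reproduces DZIOP (≤1e-6 relative
  log-likelihood); degenerate hurdles reproduce OP (≤1e-8);
* recovery: single replicate at n = 20,000 — DZIOP against
  simulation-based SEs (8 further replicates), DZIOPC at 500 GHK draws
  against sandwich SEs; every parameter within 3 SEs;
* posterior attribution: averaged posterior shares match realized latent
  zero-type fractions within 3 binomial SEs;
* misspecification: on double-hurdle data with ~30% misreporting
  participants, OP and ZIOP understate participation prevalence
  (−0.18 and −0.08 at the preset) while DZIOP is unbiased within noise;
* independence-test size: 100 null replicates at n = 2,000 with 32-draw
  GHK; empirical size must lie in the exact binomial 95% band
  [0.01, 0.11] around the nominal 5%.

## Known limitations

* Weak identification is intrinsic, not numerical: without strong
  misreporting instruments the nonparticipation/misreporting split rests
  on functional form, the likelihood ridge is nearly flat, and Wald
  standard errors understate the sampling spread along it.
* ρ_ry and ρ_my are weakly identified in all designs we tried; their
  estimates should be read with their (large) standard errors.
* Analytic scores are not implemented; everything differentiates the
  likelihood numerically.  Survey weights, panel data and Bayesian
  estimation are out of scope.
* GHK at very low draw counts biases strongly-correlated probabilities;
  the defaults (500 draws, antithetic scrambled Halton) keep this well
  below sampling noise at the validated sizes.
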