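# Methods

## Scientific setting

The analysis quantifies how strongly institution size influences whether a
preoperative blood test (CBC, basic metabolic panel, coagulation test, or
liver function test) is ordered in the 60 days before a low-risk surgery.
Two complementary Bayesian analyses are implemented: a conjugate
beta-binomial comparison of the two bed-size groups (<100 vs ≥100 beds),
and a hierarchical logistic regression with institution random intercepts
that adjusts the institutional effect for patient-level covariates.

## Cohort pipeline

Included surgeries: patient age 20–64 at surgery, at least 12 months of
insurance enrollment beforehand, and not an inpatient procedure combined
with additional/emergency procedures; rows with required fields missing
are dropped.  Rules are applied in a fixed order and every exclusion is
counted in a ledger mirroring a study flow diagram.  The binary outcome is
true iff any of the four test types has an order date `d` with
`0 ≤ surgery_date − d ≤ window` days.  The window is **closed on both
ends** (a same-day order and an order exactly `window` days before surgery
both count); the boundary convention is a package decision since "within
60 days" does not fix it, and the window length is configurable (default
60).  Group rates are carried as exact rationals and rounded only for
display: the packaged counts give 18993/41157 ≈ 46.1% (small), 21829/28095
≈ 77.7% (large), and 40822/69252 ≈ 58.95%, displayed as 59.0%.
Institution operation-volume quartiles are nearest-rank quartiles of
institution-level surgery counts computed within the cohort; tied counts
share a quartile.

## Conjugate comparison and the credible interval for a difference

With uniform Beta(1, 1) priors the group posteriors are
Beta(1 + z, n − z + 1).  The difference `D = p_large − p_small` has
density `f_D(d) = ∫ f_L(p) f_S(p − d) dp`, evaluated by Gauss–Legendre
quadrature per grid point on the intersection of the two effective
supports; beta log-densities are computed through log-gamma so that
parameters of order 2×10⁴ do not overflow.  The grid spans ±8 posterior
standard deviations of `D` around the point estimate (clipped to [−1, 1])
at 4,097 points and is doubled until both interval endpoints move by less
than 10⁻⁵.  The 95% interval is **equal-tailed** (by CDF inversion);
highest-posterior-density intervals are reserved for the MCMC summaries,
matching the way the two interval types are used in this analysis.  The
density must integrate to 1 within 10⁻⁶ or the computation aborts with a
numerical-failure error.  A 10⁶-draw Monte Carlo oracle agrees with the
convolution interval to 5×10⁻⁴ in the test suite.

## The exact Bayesian index

`θ = P(p₁ < p₂)` for independent beta posteriors has the closed form

    θ = B(a₁+a₂, b₂) / (a₁ · B(a₁,b₁) · B(a₂,b₂))
        · ₃F₂(a₁, 1−b₁, a₁+a₂ ; 1+a₁, a₁+a₂+b₂ ; 1)

with the generalized hypergeometric series at unity.  Convergence needs
the denominator-parameter sum to exceed the numerator sum, which reduces
to `b₁ + b₂ > 0` and always holds; it is asserted anyway.  Numerically the
series is treacherous:

- Terms are built by the recursive ratio
  `T_{t+1}/T_t = (a₁+t)(1−b₁+t)(a₁+a₂+t) / ((1+a₁+t)(a₁+a₂+b₂+t)(1+t))`,
  never by recomputing rising factorials, and all beta/prefactor terms are
  accumulated in log space.
- When `b₁` is a positive integer the factor `(1−b₁)_t` vanishes for
  `t ≥ b₁`: the series is exactly finite and this is detected and
  exploited (for the packaged counts the evaluated orientation terminates
  after 6,267 terms).
- The series alternates in sign and its terms can exceed the sum by
  thousands of orders of magnitude (with the packaged counts the terms
  peak near e^3152 while the sum is of order e^−2457).  The evaluator
  first profiles the series in double precision (magnitudes only), then
  sums in doubles when the cancellation fits in 50 bits and otherwise in
  arbitrary-precision arithmetic (mpmath) at exactly the precision the
  cancellation requires.
- Four algebraically equivalent orientations exist: `θ` directly, `1 − θ`
  by complementarity, and both again through the mirror identity
  `P(p₁<p₂) = P(1−p₂ < 1−p₁)`, which swaps the roles of the a and b
  parameters.  Tail decay goes as `t^−(b₁+b₂+1)` (or `t^−(a₁+a₂+1)`
  mirrored), so the evaluator profiles all four and sums the cheapest
  (terms × precision).  Non-terminating tails get an Euler–Maclaurin
  power-law tail correction, and the reported truncation bound is the
  residual after that correction.
- θ is reported as `P(p_small-bed < p_large-bed)` with explicit group
  labels throughout; two decimals in reports, full double precision in
  JSON.

Two independent oracles ship with the package and are exercised in the
tests: adaptive quadrature of `∫ f(x; a₂,b₂) I_x(a₁,b₁) dx` and paired
Monte Carlo draws with a reported standard error.

## Hierarchical logistic model and sampler

    logit π_ij = β₀ + Σ_k β_k x_kij + c_i
    β_k ~ N(0, 1000),   c_i ~ N(0, σ₀²),   σ₀² ~ Gamma(0.001, rate 0.001)

The likelihood is the product-Bernoulli form, so collapsing rows to
binomial sufficient statistics per (institution × covariate pattern) is an
algebraic identity, verified to 10⁻¹⁰ in tests; all fits run on the
aggregated form.  The fixed-effect prior variance defaults to 1000 and is
configurable (10,000 is indistinguishable at these data sizes).  The
gamma hyperprior is on the variance itself; the diffuse rate-0.001 form
(scale 1000, prior mean 1) is used — a scale of 0.001 would put prior mass
e^−1000σ² and silently erase the random effects.

Sampling is component-wise random-walk Metropolis–Hastings:

- each fixed effect is a scalar block;
- the institution intercepts are proposed jointly with independent
  per-institution accept/reject (valid because the `c_i` are conditionally
  independent given `β` and `σ₀²`);
- `σ₀²` moves on the log scale with the Jacobian correction;
- **recentering moves**: for every design column constant within
  institutions (the intercept, bed-size class, teaching status) the shift
  `β_k → β_k + δ`, `c_i → c_i − δ·x_ik` leaves every linear predictor
  unchanged, so the move is accepted on the priors alone and costs no
  likelihood evaluation.  Five sweeps per iteration repair the otherwise
  severe ridge autocorrelation between institution-level coefficients and
  the random intercepts (effective sample sizes rise from ~10 to ~2,500
  per 10,000 iterations in the recovery studies).

Proposal scales adapt toward a 20–40% acceptance band during burn-in only
and are frozen afterwards, so the retained draws come from a fixed-kernel
chain.  Defaults mirror the published run: 20,000 iterations, 500 burn-in,
no thinning, single chain (multiple chains are available and recommended
together with the diagnostics module).  Initialization is β = 0, c = 0,
σ₀² = 1.  Summaries report the posterior mean of each β as `exp(β)` (odds
ratio) with the 95% HPD computed on the β scale by the Chen–Shao
sliding-window method and exponentiated (order-preserving).

## Synthetic cohort generator

The generator emulates the structure the inference assumes — it *is* the
generative model above plus claims plumbing:

- ~69,252 surgeries over ~9,922 institutions by default; surgeries are
  allocated by a symmetric Dirichlet (concentration
  `institution_size_dispersion`, default 0.5) and multinomial assignment,
  one knob for the heavy right skew of surgeries per institution.
- A `prop_large` fraction of institutions (default 0.406) gets ≥100 beds;
  bed counts are log-uniform on [10, 99] and [100, 1000] (only the
  dichotomy matters downstream).  Institution intercepts are i.i.d.
  N(0, σ₀²), default σ₀² = 1 as a typical between-institution
  heterogeneity on the log-odds scale.
- Binary patient covariates are drawn independently at their published
  per-surgery marginals (female 0.570, outpatient 0.690, ...); default
  effect sizes are the published adjusted odds ratios on the log scale.
  Mutually exclusive anesthesia categories are approximated as
  independent flags — only marginals are published, and covariate
  correlation is out of scope.
- The intercept defaults to a calibrated value solving
  `E[logistic(β₀ + Σβ_k x_k + c)] = 0.59` (the published overall testing
  prevalence) by exact enumeration of the independent covariate sum and
  Gauss–Hermite integration over `c`, with a deterministic root-find.
- Dates: surgeries uniform over the 4-year study window (2012-04-01 to
  2016-03-31).  A positive latent testing event places each test type
  with its conditional ordering probability (per-test prevalence divided
  by overall prevalence) at `surgery − U{0..60}` days, forcing a CBC if
  none was drawn; negatives place any orders at
  `surgery − (60 + U{1..300})`.  The window rule therefore recovers the
  latent outcome exactly, which the tests assert.
- Identical config (including seed) gives bit-identical tables.

What the generator does **not** emulate: covariate correlation, repeat
surgeries per patient, coding systems (ICD-10/ATC/K codes), inter-test
correlation beyond the single latent ordering event, or secular trends.
Passing recovery tests therefore demonstrate correctness of the inference
machinery under the assumed model, not robustness to real-data violations
of it.

## Test-scale choices and tolerances

Simulation sizes in the test suite are chosen to keep the full suite in a
few minutes while leaving the checks well-powered: recovery studies use 20
replicates of 50 institutions × 20,000 surgeries with 10,000 MH iterations
(2,000 burn-in); the sampler-correctness check compares ~59,000 thinned
draws of a one-parameter model to a deterministic quadrature posterior
(KS < 0.02); the prevalence check uses a tolerance from the law of total
variance (binomial plus Dirichlet cluster-design variance), since pure
binomial error understates the design variance of a clustered cohort.
Recovery coverage is assessed at the 90% threshold pooled over the 80
replicate×coefficient intervals; a per-coefficient check at 20 replicates
would reject a perfectly calibrated sampler in roughly a quarter of seed
sets by binomial noise alone, so the pooled form tests the same property
with a ~1% false-alarm rate (a per-coefficient 80% floor still catches a
single broken coefficient).

## Known limitations

- Random-walk MH mixes slowly for the per-institution intercepts in very
  large cohorts; the diagnostics module (ESS, autocorrelation, split
  R-hat, default flags ESS < 100 or R-hat > 1.05) should accompany every
  fit, and multiple chains with thinning are advisable.
- The convolution credible interval assumes both posteriors are proper
  betas with parameters ≥ 1 in its endpoint handling; extremely small
  fractional parameters (< 0.5) are better served by the MC oracle.
- The exact-series evaluator can decline pathological non-integer
  parameter combinations (very slow tail decay with extreme cancellation)
  and recommends the quadrature method in its error message.
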