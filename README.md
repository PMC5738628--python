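# preopbayes

Bayesian analysis of institution-level determinants of preoperative blood
testing before low-risk surgery.

Routine preoperative blood tests (CBC, basic metabolic panel, coagulation
tests, liver function tests) before low-risk procedures are discouraged by
Choosing Wisely-style guidance, yet remain common.  A nationwide Japanese
claims cohort (69,252 low-risk surgeries at 9,922 institutions, patients
aged 20–64, outcome = any of the four tests ordered within 60 days before
the index procedure) showed the strongest determinant to be institution
size.  This package reimplements that analysis as a tested, reusable
library for biostatisticians and health-services researchers:

- **Conjugate beta-binomial comparison of two institution groups.**  With
  `z_i` tests out of `n_i` surgeries and a uniform Beta(1, 1) prior, each
  group's testing rate has posterior Beta(1 + z_i, n_i − z_i + 1).  The
  difference `D = p_large − p_small` gets a point estimate and an exact
  95% equal-tailed credible interval by numerical convolution of the two
  beta densities and CDF inversion (validated against a 10⁶-draw Monte
  Carlo oracle).
- **The exact Bayesian index** `θ = P(p_small < p_large | data)`
  (Kawasaki–Miyaoka), through the closed form

  `θ = B(a₁+a₂, b₂) / (a₁ B(a₁,b₁) B(a₂,b₂)) · ₃F₂(a₁, 1−b₁, a₁+a₂; 1+a₁, a₁+a₂+b₂; 1)`

  summed by recursive term ratios in log space, with automatic orientation
  selection (complementarity and the mirror identity `p → 1−p`) and
  escalation to arbitrary-precision arithmetic when the alternating series
  cancels beyond double precision.  Independent quadrature and Monte Carlo
  oracles are built in.
- **A two-level Bayesian logistic mixed model** — fixed effects with
  N(0, 1000) priors, institution random intercepts `c ~ N(0, σ₀²)`, a
  diffuse gamma hyperprior on σ₀² — fitted by component-wise random-walk
  Metropolis–Hastings (20,000 iterations, 500 burn-in by default), with
  posterior-mean odds ratios `exp(β_k)` and 95% highest-posterior-density
  intervals.
- **A synthetic claims-cohort generator.**  The source claims database is
  proprietary, so the package generates cohorts with the assumed
  statistical structure (clustered surgeries, published covariate
  marginals and effect sizes, per-test order dates honouring the 60-day
  window) for testing and parameter-recovery studies.
- **Cohort pipeline and MCMC diagnostics** — inclusion/exclusion rules
  with an exclusion ledger, the bed-size 2×2 table, autocorrelation,
  effective sample size, split R-hat.

## Worked example

```python
from preopbayes import *

table = published_bedsize_table()          # packaged 2x2 counts
prior = BetaParams(1, 1)
small = update(prior, table.z_small, table.n_small, "beds<100")
large = update(prior, table.z_large, table.n_large, "beds>=100")

print(f"small-bed posterior: Beta({small.a:.0f}, {small.b:.0f})")
print(f"large-bed posterior: Beta({large.a:.0f}, {large.b:.0f})")
print(f"rate difference:     {diff_mean(small, large):.3f}")
ci = diff_credible_interval(small, large, level=0.95)
print(f"95% CrI:             [{ci.lower:.3f}, {ci.upper:.3f}]")
res = theta_exact(small, large)
print(f"Bayesian index:      {res.theta:.2f}  ({res.method}, {res.terms_used} terms)")
fit = univariate_fit(table, n_iter=20_000, burn_in=500, seed=1)
row = fit.loc["beds_ge_100"]
print(f"univariate OR:       {row['or']:.2f}  95% HPD [{row['hpd_lower']:.2f}, {row['hpd_upper']:.2f}]")
```

prints

```
small-bed posterior: Beta(18994, 22165)
large-bed posterior: Beta(21830, 6267)
rate difference:     0.315
95% CrI:             [0.309, 0.322]
Bayesian index:      1.00  (exact-series, 6267 terms)
univariate OR:       4.06  95% HPD [3.93, 4.20]
```

Read: institutions with ≥100 beds test 31.5 percentage points more often
than those with <100 beds (posterior rates 77.7% vs 46.1%), the posterior
probability that the large-bed rate exceeds the small-bed rate is 1.00 to
two decimals, and the univariate Bayesian logistic fit puts the odds ratio
for institution size at 4.06.

A command-line interface mirrors the library:
`preopbayes simulate | tabulate | betadiff | bayes-index | fit-glmm | diagnose`
(see `preopbayes --help`).

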