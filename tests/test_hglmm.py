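"""Bayesian logistic mixed model: log-posterior algebra, sampler
correctness against analytic oracles, HPD intervals, and parameter
recovery on synthetic cohorts."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

from preopbayes import (
    BinomialData,
    GlmmSpec,
    TwoByTwo,
    aggregate_cohort,
    build_cohort,
    hpd_interval,
    log_posterior,
    mh_sample,
    summarize,
    univariate_fit,
)
from preopbayes.exceptions import InsufficientSamplesError, ParameterError
from preopbayes.simulate import SyntheticConfig, generate_cohort


def random_cohort_frame(rng, n=200, n_inst=8):
    return pd.DataFrame(
        {
            "institution_id": rng.integers(0, n_inst, n),
            "x1": rng.random(n) < 0.5,
            "x2": rng.random(n) < 0.3,
            "outcome": rng.random(n) < 0.4,
        }
    )


class TestLogPosterior:
    def test_prior_only_matches_closed_form(self):
        """No data: the log-posterior is the sum of the normal and gamma
        log-densities, checked against scipy's closed forms."""
        spec = GlmmSpec(predictors=("x1",))
        beta = np.array([0.3, -0.2])
        c = np.array([0.1, -0.4, 0.2])
        sig = 1.7
        expected = (
            stats.norm.logpdf(beta, 0.0, math.sqrt(1000.0)).sum()
            + stats.norm.logpdf(c, 0.0, math.sqrt(sig)).sum()
            + stats.gamma.logpdf(sig, a=0.001, scale=1000.0)
        )
        got = log_posterior(beta, c, sig, None, spec)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_aggregated_equals_rowwise(self):
        """Collapsing rows to binomial sufficient statistics is an algebraic
        identity for the product-Bernoulli likelihood."""
        rng = np.random.default_rng(3)
        cohort = random_cohort_frame(rng)
        spec = GlmmSpec(predictors=("x1", "x2"))
        agg = aggregate_cohort(cohort, ["x1", "x2"])
        # row-wise: every surgery is its own binomial row with n=1
        rowwise = BinomialData(
            X=np.column_stack(
                [np.ones(len(cohort)), cohort["x1"], cohort["x2"]]
            ).astype(float),
            z=cohort["outcome"].to_numpy(dtype=float),
            n=np.ones(len(cohort)),
            inst_idx=pd.factorize(cohort["institution_id"], sort=True)[0],
            n_institutions=cohort["institution_id"].nunique(),
        )
        beta = np.array([0.2, -0.5, 0.9])
        c = rng.normal(0, 0.5, agg.n_institutions)
        a = log_posterior(beta, c, 0.8, agg, spec)
        b = log_posterior(beta, c, 0.8, rowwise, spec)
        assert a == pytest.approx(b, abs=1e-10)

    def test_zero_state_loglik_is_n_log_half(self):
        rng = np.random.default_rng(5)
        cohort = random_cohort_frame(rng, n=150)
        spec = GlmmSpec(predictors=("x1", "x2"))
        agg = aggregate_cohort(cohort, ["x1", "x2"])
        beta = np.zeros(3)
        c = np.zeros(agg.n_institutions)
        prior = log_posterior(beta, c, 1.0, None, spec)
        full = log_posterior(beta, c, 1.0, agg, spec)
        assert full - prior == pytest.approx(150 * math.log(0.5), abs=1e-9)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(11)
        cohort = random_cohort_frame(rng)
        spec = GlmmSpec(predictors=("x1", "x2"))
        shuffled = cohort.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = aggregate_cohort(cohort, ["x1", "x2"])
        b = aggregate_cohort(shuffled, ["x1", "x2"])
        beta = np.array([0.1, 0.4, -0.3])
        c = rng.normal(0, 1, a.n_institutions)
        assert log_posterior(beta, c, 0.5, a, spec) == pytest.approx(
            log_posterior(beta, c, 0.5, b, spec), abs=1e-10
        )

    def test_nonpositive_variance_is_rejected_region(self):
        spec = GlmmSpec(predictors=())
        assert log_posterior(np.zeros(1), np.zeros(2), 0.0, None, spec) == -np.inf


class TestSampler:
    def test_seed_determinism(self):
        data = BinomialData(
            X=np.array([[1.0, 0.0], [1.0, 1.0]]),
            z=np.array([30.0, 60.0]),
            n=np.array([100.0, 100.0]),
        )
        spec = GlmmSpec(predictors=("x",))
        a = mh_sample(data, spec, n_iter=500, burn_in=100, seed=4)
        b = mh_sample(data, spec, n_iter=500, burn_in=100, seed=4)
        c = mh_sample(data, spec, n_iter=500, burn_in=100, seed=5)
        assert np.array_equal(a.draws["x"], b.draws["x"])
        assert not np.array_equal(a.draws["x"], c.draws["x"])

    def test_matches_conjugate_oracle_on_one_parameter_model(self):
        """Intercept-only model, z/n = 30/100.  The exact posterior of
        expit(beta0) under the actual N(0,1000) prior is computed by
        deterministic quadrature (it is Beta(30,70) up to a negligible
        tilt from the prior); the chain must match in distribution
        (Kolmogorov-Smirnov) and in mean."""
        data = BinomialData(
            X=np.ones((1, 1)), z=np.array([30.0]), n=np.array([100.0])
        )
        spec = GlmmSpec(predictors=())
        chains = mh_sample(data, spec, n_iter=120_000, burn_in=2_000, thin=2, seed=8)
        p_draws = expit(chains.draws["intercept"])
        assert len(p_draws) >= 50_000

        # quadrature oracle on the beta0 scale
        grid = np.linspace(-3.5, 1.5, 20_001)
        log_post = (
            30.0 * grid
            - 100.0 * np.logaddexp(0.0, grid)
            + stats.norm.logpdf(grid, 0.0, math.sqrt(1000.0))
        )
        dens = np.exp(log_post - log_post.max())
        cdf = np.concatenate([[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1]) * np.diff(grid))])
        cdf /= cdf[-1]
        ks = np.max(
            np.abs(
                np.interp(np.sort(chains.draws["intercept"]), grid, cdf)
                - (np.arange(1, len(p_draws) + 1)) / len(p_draws)
            )
        )
        assert ks < 0.02

        p_grid = expit(grid)
        oracle_mean = np.trapezoid(p_grid * dens, grid) / np.trapezoid(dens, grid)
        assert p_draws.mean() == pytest.approx(oracle_mean, abs=0.004)
        # the uniform-on-p conjugate answer Beta(31,71) is nearby
        assert abs(oracle_mean - 31 / 102) < 0.006

    def test_initialization_error_message(self):
        data = BinomialData(
            X=np.ones((1, 1)), z=np.array([3.0]), n=np.array([10.0])
        )
        spec = GlmmSpec(predictors=())
        with pytest.raises(ParameterError, match="initialization"):
            mh_sample(data, spec, n_iter=100, burn_in=10, init_beta=[np.inf])

    def test_iteration_validation(self):
        data = BinomialData(X=np.ones((1, 1)), z=np.array([1.0]), n=np.array([2.0]))
        with pytest.raises(ParameterError):
            mh_sample(data, GlmmSpec(), n_iter=100, burn_in=100)


class TestHpd:
    def test_constant_samples_zero_width(self):
        iv = hpd_interval(np.full(500, 2.5))
        assert iv.lower == iv.upper == 2.5
        assert iv.kind == "HPD"

    def test_standard_normal_quantiles(self):
        rng = np.random.default_rng(100)
        x = rng.standard_normal(10**6)
        iv = hpd_interval(x, 0.95)
        assert iv.lower == pytest.approx(-1.96, abs=0.01)
        assert iv.upper == pytest.approx(1.96, abs=0.01)

    def test_never_wider_than_equal_tailed(self):
        rng = np.random.default_rng(55)
        for _ in range(10):
            x = rng.gamma(2.0, 1.0, 400)
            iv = hpd_interval(x, 0.9)
            lo, hi = np.quantile(x, [0.05, 0.95])
            assert iv.width <= (hi - lo) + 1e-12

    def test_matches_brute_force_windows(self):
        """Exhaustive search over contiguous windows on a small sample."""
        rng = np.random.default_rng(77)
        x = np.sort(rng.normal(0, 1, 120))
        iv = hpd_interval(x, 0.8)
        w = math.ceil(0.8 * len(x))
        best = min(
            (x[i + w] - x[i], x[i], x[i + w]) for i in range(len(x) - w)
        )
        assert iv.lower == best[1] and iv.upper == best[2]

    def test_too_few_samples(self):
        with pytest.raises(InsufficientSamplesError):
            hpd_interval(np.arange(50))


class TestUnivariateFit:
    def test_published_counts_reproduce_or(self, bedsize_table):
        """The beds-only Bayesian logistic fit lands on the published
        univariate odds ratio 4.06 (posterior-mean, MC tolerance)."""
        s = univariate_fit(bedsize_table, seed=2024)
        t = bedsize_table
        crude = (t.z_large * (t.n_small - t.z_small)) / (
            t.z_small * (t.n_large - t.z_large)
        )
        assert s.loc["beds_ge_100", "or"] == pytest.approx(4.06, abs=0.05)
        assert s.loc["beds_ge_100", "or"] == pytest.approx(crude, abs=0.05)
        assert s.loc["beds_ge_100", "hpd_lower"] < 4.06 < s.loc["beds_ge_100", "hpd_upper"]

    def test_symmetric_table_gives_unit_or(self):
        t = TwoByTwo(z_small=400, n_small=1000, z_large=400, n_large=1000)
        s = univariate_fit(t, n_iter=8_000, burn_in=500, seed=6)
        assert s.loc["beds_ge_100", "or"] == pytest.approx(1.0, abs=0.1)

    def test_posterior_concentrates_with_count_scale(self):
        base = TwoByTwo(z_small=46, n_small=100, z_large=78, n_large=100)
        big = TwoByTwo(z_small=4600, n_small=10_000, z_large=7800, n_large=10_000)
        crude = (78 * 54) / (22 * 46)
        s1 = univariate_fit(base, n_iter=8_000, burn_in=500, seed=7)
        s2 = univariate_fit(big, n_iter=8_000, burn_in=500, seed=7)
        w1 = s2.loc["beds_ge_100", "hpd_upper"] - s2.loc["beds_ge_100", "hpd_lower"]
        w0 = s1.loc["beds_ge_100", "hpd_upper"] - s1.loc["beds_ge_100", "hpd_lower"]
        assert w1 < w0 / 5
        assert s2.loc["beds_ge_100", "or"] == pytest.approx(crude, rel=0.03)

    def test_zero_margin_warns_but_fits(self):
        t = TwoByTwo(z_small=0, n_small=50, z_large=20, n_large=50)
        with pytest.warns(UserWarning, match="zero"):
            s = univariate_fit(t, n_iter=2_000, burn_in=200, seed=9)
        assert np.isfinite(s.loc["beds_ge_100", "or"])


class TestSummarize:
    def test_degenerate_chain_gives_exact_or(self):
        data = BinomialData(
            X=np.array([[1.0, 0.0], [1.0, 1.0]]),
            z=np.array([30.0, 60.0]),
            n=np.array([100.0, 100.0]),
        )
        spec = GlmmSpec(predictors=("x",))
        chains = mh_sample(data, spec, n_iter=400, burn_in=100, seed=1)
        chains.draws["x"] = np.full(chains.n_kept, math.log(2.0))
        s = summarize(chains, spec)
        assert s.loc["x", "or"] == pytest.approx(2.0, abs=1e-12)
        assert s.loc["x", "hpd_lower"] == pytest.approx(2.0)
        assert s.loc["x", "hpd_upper"] == pytest.approx(2.0)


class TestRecovery:
    def test_hpd_coverage_and_variance_recovery(self):
        """Parameter recovery across 20 replicate synthetic cohorts: each
        true fixed effect is inside its 95% HPD in at least 90% of
        replicates, and the pooled posterior mean of sigma0_sq is within
        50% of the truth."""
        true = {"female": 0.3, "outpatient": -0.8, "beds_ge_100": 1.0}
        true_b0 = -0.4
        sig_true = 0.5
        preds = ["female", "outpatient", "beds_ge_100"]
        spec = GlmmSpec(predictors=tuple(preds))
        names = ["intercept", *preds]
        truth = {"intercept": true_b0, **true}
        cover = {k: 0 for k in names}
        sig_means = []
        n_rep = 20
        for rep in range(n_rep):
            cfg = SyntheticConfig(
                n_patients=20_000,
                n_institutions=50,
                prop_large=0.4,
                institution_size_dispersion=5.0,
                covariate_marginals={"female": 0.5, "outpatient": 0.6},
                true_beta=true,
                true_intercept=true_b0,
                sigma0_sq=sig_true,
                seed=1_000 + rep,
            )
            cohort, _ = build_cohort(generate_cohort(cfg))
            data = aggregate_cohort(cohort, preds)
            chains = mh_sample(data, spec, n_iter=10_000, burn_in=2_000, seed=rep)
            for name in names:
                hpd = hpd_interval(chains.draws[name], 0.95)
                if hpd.lower <= truth[name] <= hpd.upper:
                    cover[name] += 1
            sig_means.append(chains.draws["sigma0_sq"].mean())
        for name in names:
            assert cover[name] >= 0.9 * n_rep, (name, cover)
        pooled = float(np.mean(sig_means))
        assert abs(pooled - sig_true) / sig_true < 0.5
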