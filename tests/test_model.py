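import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rsfkit.model import (
    BayesianLassoRSF,
    ModelConfig,
    gelman_rubin,
    group_contrast,
    influence_flags,
    log_posterior,
    posterior_summary,
    update_lambda_gibbs,
)

REDUCED = dict(iterations=5000, burn_in=2500, thin=5)


def logistic_data(n=600, beta=(1.0, -0.5), b0=-1.0, seed=0):
    rng = np.random.default_rng(seed)
    beta = np.asarray(beta)
    X = rng.standard_normal((n, beta.size))
    p = 1.0 / (1.0 + np.exp(-(b0 + X @ beta)))
    y = rng.binomial(1, p)
    cols = [f"v{i}" for i in range(beta.size)]
    return pd.DataFrame(X, columns=cols), y


# ---------------------------------------------------------------------------
# log posterior
# ---------------------------------------------------------------------------

class TestLogPosterior:
    def test_null_state_likelihood_is_minus_n_log2(self):
        X = np.zeros((4, 2))
        y = np.array([1.0, 0.0, 1.0, 0.0])
        lam, a, b = 1.0, 0.01, 0.01
        lp = log_posterior(0.0, [0.0, 0.0], lam, X, y, a=a, b=b)
        priors = (2 * np.log(lam / 2.0)
                  + stats.gamma.logpdf(lam, a, scale=1.0 / b)
                  + stats.norm.logpdf(0.0, 0.0, 10.0))
        assert lp - priors == pytest.approx(-4.0 * np.log(2.0), abs=1e-10)

    def test_matches_term_by_term_oracle_on_three_rows(self):
        """Independent evaluation with scipy distributions, to 1e-10."""
        rng = np.random.default_rng(12)
        X = rng.standard_normal((3, 2))
        y = np.array([1.0, 0.0, 1.0])
        beta0, beta, lam = 0.3, np.array([0.8, -1.2]), 0.7
        gamma = np.array([0.2, -0.1])
        groups = np.array([0, 1, 0])
        sig, U, isd, a, b = 0.9, 10.0, 10.0, 0.01, 0.01

        eta = beta0 + X @ beta + gamma[groups]
        p = 1.0 / (1.0 + np.exp(-eta))
        oracle = float(np.sum(stats.bernoulli.logpmf(y.astype(int), p)))
        oracle += float(np.sum(stats.laplace.logpdf(beta, scale=1.0 / lam)))
        oracle += float(stats.gamma.logpdf(lam, a, scale=1.0 / b))
        oracle += float(stats.norm.logpdf(beta0, 0.0, isd))
        oracle += float(np.sum(stats.norm.logpdf(gamma, 0.0, sig)))
        oracle += float(stats.uniform.logpdf(sig, 0.0, U))

        got = log_posterior(beta0, beta, lam, X, y, a=a, b=b, gamma=gamma,
                            groups=groups, sigma_gamma=sig, re_upper=U,
                            intercept_sd=isd)
        assert got == pytest.approx(oracle, abs=1e-10)

    def test_doubling_lambda_shifts_laplace_part_algebraically(self):
        X = np.zeros((2, 3))
        y = np.array([1.0, 0.0])
        beta = np.array([0.5, -1.0, 2.0])
        lam, a, b = 0.8, 0.01, 0.01
        gamma_shift = (stats.gamma.logpdf(2 * lam, a, scale=1 / b)
                       - stats.gamma.logpdf(lam, a, scale=1 / b))
        diff = (log_posterior(0.0, beta, 2 * lam, X, y, a=a, b=b)
                - log_posterior(0.0, beta, lam, X, y, a=a, b=b)) - gamma_shift
        expected = 3 * np.log(2.0) - lam * np.abs(beta).sum()
        assert diff == pytest.approx(expected, abs=1e-10)

    def test_nonfinite_covariates_rejected(self):
        with pytest.raises(ValueError):
            log_posterior(0.0, [1.0], 1.0, np.array([[np.inf]]), [1.0])


# ---------------------------------------------------------------------------
# lambda Gibbs
# ---------------------------------------------------------------------------

class TestLambdaGibbs:
    def test_monte_carlo_mean_matches_conjugate_algebra(self):
        """K=2, sum|beta|=2, a=b=0.01 => Gamma(2.01, 2.01); MC mean of 1e5
        draws within 1% of the analytic mean."""
        rng = np.random.default_rng(0)
        beta = np.array([1.5, -0.5])
        draws = np.array([update_lambda_gibbs(beta, 0.01, 0.01, rng)
                          for _ in range(100_000)])
        assert draws.mean() == pytest.approx(2.01 / 2.01, rel=0.01)

    def test_conditional_matches_density_ratio_of_log_posterior(self):
        """The full conditional's density ratio at two lambda values equals
        the log-posterior difference, for arbitrary states."""
        rng = np.random.default_rng(5)
        X = rng.standard_normal((6, 3))
        y = (rng.random(6) < 0.5).astype(float)
        beta = rng.standard_normal(3)
        a, b = 0.01, 0.01
        sab = np.abs(beta).sum()
        for l1, l2 in [(0.3, 1.7), (2.0, 0.05)]:
            lp_ratio = (log_posterior(0.1, beta, l1, X, y, a=a, b=b)
                        - log_posterior(0.1, beta, l2, X, y, a=a, b=b))
            cond_ratio = (stats.gamma.logpdf(l1, a + 3, scale=1 / (b + sab))
                          - stats.gamma.logpdf(l2, a + 3, scale=1 / (b + sab)))
            assert lp_ratio == pytest.approx(cond_ratio, abs=1e-10)

    def test_shrinkage_releases_as_betas_grow(self):
        rng = np.random.default_rng(1)
        small = np.mean([update_lambda_gibbs([0.1, 0.1], rng=rng)
                         for _ in range(2000)])
        large = np.mean([update_lambda_gibbs([10.0, 10.0], rng=rng)
                         for _ in range(2000)])
        assert large < small


# ---------------------------------------------------------------------------
# convergence diagnostic
# ---------------------------------------------------------------------------

class TestGelmanRubin:
    def test_identical_chains_give_sqrt_three_quarters(self):
        chains = np.array([[1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0]])
        rhat, flags = gelman_rubin({"p": chains})
        assert rhat["p"] == pytest.approx(np.sqrt(3.0 / 4.0))
        assert not flags["p"]

    def test_same_distribution_long_chains_near_one(self):
        rng = np.random.default_rng(2)
        chains = rng.standard_normal((3, 20_000))
        rhat, _ = gelman_rubin(chains)
        assert 0.99 <= rhat["param"] <= 1.02

    def test_constant_disjoint_chains_flagged_undefined(self):
        chains = np.array([[0.0, 0.0, 0.0], [5.0, 5.0, 5.0]])
        rhat, flags = gelman_rubin({"p": chains})
        assert np.isnan(rhat["p"]) and flags["p"]

    def test_agrees_with_arviz_on_mixed_chains(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(3)
        chains = rng.standard_normal((4, 2000)) + 0.05 * np.arange(4)[:, None]
        ours = gelman_rubin(chains)[0]["param"]
        theirs = float(az.rhat(az.convert_to_dataset(chains))["x"])
        assert ours == pytest.approx(theirs, abs=0.05)


# ---------------------------------------------------------------------------
# posterior utilities
# ---------------------------------------------------------------------------

def test_influence_flags_boundary_inclusive():
    assert influence_flags({"pos": np.ones(100)}) == {"pos"}
    sym = np.concatenate([np.ones(50), -np.ones(50)])
    assert influence_flags({"sym": sym}) == set()
    boundary = np.concatenate([np.ones(85), -np.ones(15)])
    assert influence_flags({"edge": boundary}) == {"edge"}


def test_group_contrast_paired_fractions():
    assert group_contrast([1, 2, 3], [0, 1, 2]) == 1.0
    assert group_contrast([0, 1], [1, 0]) == 0.5
    with pytest.raises(ValueError):
        group_contrast([1, 2, 3], [1, 2])


def test_posterior_summary_examples():
    s = posterior_summary({"a": np.array([1.0, 2.0, 3.0]),
                           "b": np.full(10, 4.0)})
    assert s.loc["a", "median"] == 2.0
    assert s.loc["b", "ci95_low"] == s.loc["b", "ci95_high"] == 4.0
    rng = np.random.default_rng(4)
    big = posterior_summary({"z": rng.standard_normal(100_000)})
    assert big.loc["z", "ci95_low"] == pytest.approx(-1.96, abs=0.05)
    assert big.loc["z", "ci95_high"] == pytest.approx(1.96, abs=0.05)


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

class TestFit:
    def test_retained_draw_bookkeeping(self):
        X, y = logistic_data(n=200, seed=1)
        m = BayesianLassoRSF(chains=2, iterations=1000, burn_in=400, thin=3,
                             random_state=0).fit(X, y)
        assert m.posterior_["beta"].shape == (2, 200, 2)

    def test_same_seeds_reproduce_draws_exactly(self):
        X, y = logistic_data(n=200, seed=2)
        kw = dict(chains=2, iterations=800, burn_in=400, random_state=11)
        a = BayesianLassoRSF(**kw).fit(X, y)
        b = BayesianLassoRSF(**kw).fit(X, y)
        assert np.array_equal(a.posterior_["beta"], b.posterior_["beta"])
        assert np.array_equal(a.posterior_["lambda"], b.posterior_["lambda"])

    def test_pure_noise_covariate_is_shrunk(self):
        rng = np.random.default_rng(60)
        X, y = logistic_data(n=800, beta=(1.2,), seed=6)
        X["noise"] = rng.standard_normal(len(X))
        m = BayesianLassoRSF(chains=2, random_state=3, **REDUCED).fit(X, y)
        assert abs(m.coef_["noise"]) < abs(m.coef_["v0"]) / 3.0

    def test_posterior_matches_emcee_reference(self):
        """Independent sampler over the same unnormalized posterior: an
        ensemble sampler run on (beta0, beta, log lambda) must agree with
        our Gibbs-within-Metropolis means within Monte-Carlo error."""
        emcee = pytest.importorskip("emcee")
        X, y = logistic_data(n=300, seed=7)
        Xv = X.to_numpy()

        def logp(theta):
            b0, b1, b2, loglam = theta
            lam = np.exp(loglam)
            return log_posterior(b0, [b1, b2], lam, Xv, y) + loglam

        rng = np.random.default_rng(0)
        p0 = rng.normal(0, 0.1, size=(24, 4))
        sampler = emcee.EnsembleSampler(24, 4, logp)
        sampler.run_mcmc(p0, 3000, progress=False)
        ref = sampler.get_chain(discard=1000, flat=True)

        m = BayesianLassoRSF(chains=3, random_state=8, **REDUCED).fit(X, y)
        assert m.coef_["v0"] == pytest.approx(ref[:, 1].mean(), abs=0.05)
        assert m.coef_["v1"] == pytest.approx(ref[:, 2].mean(), abs=0.05)
        assert m.posterior_["beta0"].mean() == pytest.approx(
            ref[:, 0].mean(), abs=0.05)
        assert m.posterior_["lambda"].mean() == pytest.approx(
            np.exp(ref[:, 3]).mean(), rel=0.15)

    def test_nonconvergent_run_flags_and_warns(self):
        X, y = logistic_data(n=400, beta=(2.0, -1.5), seed=9)
        with pytest.warns(UserWarning, match="convergence"):
            m = BayesianLassoRSF(chains=3, iterations=30, burn_in=10, thin=1,
                                 random_state=5).fit(X, y)
        assert not m.converged_

    def test_input_validation(self):
        X, y = logistic_data(n=50, seed=0)
        with pytest.raises(ValueError):
            BayesianLassoRSF().fit(X, y[:-1])
        with pytest.raises(ValueError):
            BayesianLassoRSF().fit(X, y + 2)
        with pytest.raises(ValueError):
            BayesianLassoRSF(random_intercepts=True).fit(X, y)


class TestScaleIndicators:
    def test_single_candidate_has_probability_one(self):
        X, y = logistic_data(n=300, beta=(1.0,), seed=10)
        m = BayesianLassoRSF(chains=2, iterations=1000, burn_in=500,
                             scale_groups={"v": ["v0"]},
                             random_state=1).fit(X, y)
        assert m.selected_scales_["v"] == "v0"
        assert (m.posterior_["scales"] == 0).all()

    def test_identical_candidate_columns_give_uniform_probabilities(self):
        X, y = logistic_data(n=400, beta=(1.0,), seed=11)
        X = X.rename(columns={"v0": "c1"})
        X["c2"] = X["c1"]
        X["c3"] = X["c1"]
        m = BayesianLassoRSF(chains=3, scale_groups={"v": ["c1", "c2", "c3"]},
                             random_state=2, **REDUCED).fit(X, y)
        probs = m.scale_probs_.loc["v"]
        assert np.all(np.abs(probs - 1.0 / 3.0) < 0.08)
        assert probs.sum() == pytest.approx(1.0)


class TestModelConfig:
    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            ModelConfig(thin=0)
        with pytest.raises(ValueError):
            ModelConfig(lasso_a=0.0)

    def test_reduced_profile_shape(self):
        c = ModelConfig.reduced()
        assert (c.iterations, c.burn_in, c.chains) == (5000, 2500, 3)


def test_group_contrast_symmetric_under_identical_truth():
    """With identical generating coefficients for both groups, the contrast
    probability should stay away from the strong-evidence bounds
    (0.05, 0.95) in nearly all replicates."""
    inside = 0
    n_rep = 6
    for rep in range(n_rep):
        rng = np.random.default_rng(500 + rep)
        n = 600
        x = rng.standard_normal(n)
        group = np.where(rng.random(n) < 0.5, "resident", "translocated")
        p = 1.0 / (1.0 + np.exp(-(-1.0 + 1.0 * x)))  # same beta both groups
        y = rng.binomial(1, p)
        X = pd.DataFrame({
            "x|resident": np.where(group == "resident", x, 0.0),
            "x|translocated": np.where(group == "translocated", x, 0.0),
        })
        m = BayesianLassoRSF(chains=2, iterations=2000, burn_in=1000, thin=2,
                             random_state=rep).fit(X, y)
        prob = group_contrast(m.beta_draws("x|resident"),
                              m.beta_draws("x|translocated"))
        inside += int(0.05 < prob < 0.95)
    assert inside >= n_rep - 1
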