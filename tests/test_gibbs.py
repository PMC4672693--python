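import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from longcace import (ChainConfig, PriorSpec, SimConfig, generate_dataset,
                      run_gibbs)
from longcace.gibbs import (_invwishart, compliance_posterior, gelman_rubin,
                            impute_missing_outcomes, update_coefficients,
                            update_gamma, update_sigma)
from longcace.data import TrialDataset
from longcace.means import ModelParameters


def _params(alpha, beta, gamma, sigma):
    return ModelParameters(alpha=alpha, beta=beta, gamma=gamma, sigma=sigma)


class TestCompliancePosterior:
    def test_control_is_point_mass_at_observed_departure(self, true_params):
        p = compliance_posterior(np.zeros(5), r=0, d=2, params=true_params)
        assert list(p) == [0, 0, 1, 0, 0, 0]

    def test_flat_likelihood_returns_prior_weights(self):
        m = 2
        params = _params(alpha=np.full((3, 2), 4.0), beta=[1.0, 2.0],
                         gamma=[1 / 3] * 3, sigma=np.eye(2))
        p = compliance_posterior(np.array([0.0, 0.0]), r=1, d=0, params=params)
        assert p == pytest.approx(np.full(3, 1 / 3))

    def test_matches_direct_density_evaluation(self):
        # brute-force oracle: evaluate the bivariate normal densities and
        # normalise by hand
        alpha = np.array([[0.0, 0.0], [3.0, -1.0], [1.0, 2.0]])
        beta = np.array([0.5, -0.5])
        gamma = np.array([0.5, 0.25, 0.25])
        params = _params(alpha, beta, gamma, np.eye(2))
        y = np.array([0.0, 0.0])
        dens = np.array([
            gamma[c] * stats.multivariate_normal.pdf(y, alpha[c] + beta, np.eye(2))
            for c in range(3)])
        p = compliance_posterior(y, r=1, d=0, params=params)
        assert p == pytest.approx(dens / dens.sum(), abs=1e-12)

    def test_marginalises_over_missing_coordinates(self):
        alpha = np.array([[0.0, 50.0], [3.0, -50.0], [1.0, 2.0]])
        params = _params(alpha, [0.0, 0.0], [1 / 3] * 3, np.eye(2))
        y = np.array([0.5, np.nan])
        dens = np.array([stats.norm.pdf(0.5, alpha[c, 0], 1) for c in range(3)])
        p = compliance_posterior(y, r=1, d=0, params=params)
        assert p == pytest.approx(dens / dens.sum(), abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_normalised_and_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        m = 3
        g = rng.dirichlet(np.ones(m + 1))
        A = rng.normal(scale=30, size=(m + 1, m))
        params = _params(A, rng.normal(size=m), g, np.eye(m) * rng.uniform(0.5, 4))
        y = rng.normal(scale=50, size=m)  # far tails exercise log-space path
        p = compliance_posterior(y, r=1, d=0, params=params)
        assert np.all(p >= 0) and not np.isnan(p).any()
        assert p.sum() == pytest.approx(1.0, abs=1e-12)


class TestUpdateCoefficients:
    def test_single_never_treated_subject_centres_on_outcome(self, rng):
        ds = TrialDataset(arm=[0], departure=[1], outcomes=[[7.5]],
                          visit_days=[90.0])
        prior = PriorSpec(coef_prior_variance=1e12)
        (_, _), ((alpha_mean, _), _) = update_coefficients(
            ds, C=[1], Sigma=np.eye(1), prior=prior, rng=rng,
            return_moments=True)
        assert alpha_mean[1, 0] == pytest.approx(7.5, abs=1e-6)

    def test_zero_prior_variance_limit_pins_to_zero(self, rng):
        ds = TrialDataset(arm=[0], departure=[1], outcomes=[[7.5]],
                          visit_days=[90.0])
        prior = PriorSpec(coef_prior_variance=1e-12)
        alpha, beta = update_coefficients(ds, C=[1], Sigma=np.eye(1),
                                          prior=prior, rng=rng)
        assert abs(alpha).max() < 1e-4 and abs(beta).max() < 1e-4

    def test_conditional_mean_matches_gls_oracle(self, rng):
        # with all compliance types revealed the conditional mean under a
        # flat prior is the GLS fit; compare against the true curve at n=5000
        cfg = SimConfig(n=5000, base_seed=99)
        ds, C = generate_dataset(cfg, 0, return_types=True)
        _, ((_, beta_mean), _) = update_coefficients(
            ds, C=C, Sigma=64 * np.eye(5), prior=PriorSpec(), rng=rng,
            return_moments=True)
        # Monte-Carlo SE of a GLS coefficient at this n is below ~0.35
        assert np.abs(beta_mean - [10, 8, 6, 4, 2]).max() < 3 * 0.35

    def test_absent_type_falls_back_to_prior(self, rng, caplog):
        ds = TrialDataset(arm=[0, 0], departure=[2, 2],
                          outcomes=[[1.0, 2.0], [3.0, 4.0]],
                          visit_days=[90.0, 180.0])
        import logging

        with caplog.at_level(logging.WARNING, logger="longcace.gibbs"):
            alpha, _ = update_coefficients(ds, C=[2, 2], Sigma=np.eye(2),
                                           prior=PriorSpec(coef_prior_variance=1.0),
                                           rng=rng)
        assert "absent" in caplog.text
        assert np.isfinite(alpha).all()


class TestUpdateSigma:
    def test_concentrates_on_residual_covariance(self, rng):
        resid = rng.normal(scale=8.0, size=(20000, 5))
        draws = np.stack([update_sigma(resid, PriorSpec(), rng)
                          for _ in range(20)])
        mean = draws.mean(axis=0)
        assert np.abs(np.diag(mean) - 64.0).max() < 3.0
        off = mean[~np.eye(5, dtype=bool)]
        assert np.abs(off).max() < 3.0

    def test_empty_residuals_draw_from_prior(self, rng):
        prior = PriorSpec(wishart_df=10, wishart_scale=4.0 * np.eye(2))
        draws = np.stack([update_sigma(np.empty((0, 2)), prior, rng)
                          for _ in range(4000)])
        # prior mean scale/(df - m - 1) = 4/7 I
        assert draws.mean(axis=0) == pytest.approx(4.0 / 7.0 * np.eye(2), abs=0.05)

    def test_univariate_reduces_to_scaled_inverse_chisq(self, rng):
        # m=1: IW(df, s) is s * inv-chi2(df); check mean s/(df-2)
        prior = PriorSpec(wishart_df=6, wishart_scale=np.array([[10.0]]))
        draws = np.array([update_sigma(np.empty((0, 1)), prior, rng)[0, 0]
                          for _ in range(4000)])
        assert draws.mean() == pytest.approx(10.0 / 4.0, rel=0.1)
        assert (draws > 0).all()

    def test_agrees_with_scipy_invwishart(self):
        # same distribution as scipy.stats.invwishart (moment check)
        rng = np.random.default_rng(7)
        scale = np.array([[4.0, 1.0], [1.0, 3.0]])
        ours = np.stack([_invwishart(12, scale, rng) for _ in range(6000)])
        theirs = stats.invwishart(df=12, scale=scale).rvs(
            size=6000, random_state=np.random.default_rng(8))
        assert ours.mean(axis=0) == pytest.approx(theirs.mean(axis=0), rel=0.08)

    def test_draws_positive_definite(self, rng):
        resid = rng.normal(size=(50, 4))
        for _ in range(50):
            S = update_sigma(resid, PriorSpec(), rng)
            assert np.all(np.linalg.eigvalsh(S) > 0)


class TestImputeMissing:
    def test_nothing_missing_is_identity(self, rng):
        y = np.array([1.0, 2.0])
        out = impute_missing_outcomes(y, np.zeros(2), np.eye(2), rng)
        assert np.array_equal(out, y)

    def test_diagonal_covariance_ignores_observed(self, rng):
        draws = np.array([
            impute_missing_outcomes(np.array([100.0, np.nan]), np.array([0.0, 3.0]),
                                    np.diag([1.0, 0.25]), rng)[1]
            for _ in range(4000)])
        assert draws.mean() == pytest.approx(3.0, abs=0.05)
        assert draws.std() == pytest.approx(0.5, abs=0.05)

    def test_bivariate_conditional_moments(self, rng):
        # closed form: y2 | y1=2 ~ N(1, 0.75) under unit variances, corr 0.5
        Sigma = np.array([[1.0, 0.5], [0.5, 1.0]])
        draws = np.array([
            impute_missing_outcomes(np.array([2.0, np.nan]), np.zeros(2),
                                    Sigma, rng)[1]
            for _ in range(8000)])
        assert draws.mean() == pytest.approx(1.0, abs=0.05)
        assert draws.var() == pytest.approx(0.75, abs=0.05)

    def test_fully_missing_draws_unconditional(self, rng):
        draws = np.stack([
            impute_missing_outcomes(np.array([np.nan, np.nan]),
                                    np.array([5.0, -5.0]), 4 * np.eye(2), rng)
            for _ in range(4000)])
        assert draws.mean(axis=0) == pytest.approx([5.0, -5.0], abs=0.15)


class TestUpdateGamma:
    def test_flat_prior_no_data_is_symmetric_dirichlet(self, rng):
        draws = np.stack([update_gamma(np.empty(0, dtype=int), PriorSpec(),
                                       rng, m=2) for _ in range(4000)])
        assert draws.mean(axis=0) == pytest.approx(np.full(3, 1 / 3), abs=0.03)

    def test_large_counts_concentrate_at_proportions(self, rng):
        target = np.array([1, 1, 1, 1, 1, 4]) / 9
        C = np.repeat(np.arange(6), (target * 90000).astype(int))
        draws = np.stack([update_gamma(C, PriorSpec(), rng, m=5)
                          for _ in range(50)])
        assert np.abs(draws.mean(axis=0) - target).max() < 0.005

    def test_binary_case_is_beta_draw(self, rng):
        C = np.array([0, 0, 1, 1, 1], dtype=int)
        draws = np.array([update_gamma(C, PriorSpec(), rng, m=1)[1]
                          for _ in range(4000)])
        # Beta(1+3, 1+2) mean = 4/7
        assert draws.mean() == pytest.approx(4 / 7, abs=0.03)

    def test_simplex_valued(self, rng):
        for _ in range(50):
            g = update_gamma(np.array([0, 1, 2, 2]), PriorSpec(), rng, m=2)
            assert g.sum() == pytest.approx(1.0, abs=1e-12) and (g >= 0).all()


class TestRunGibbs:
    def test_identical_seeds_bit_identical_chains(self, sim_dataset):
        cfg = ChainConfig(n_iterations=150, n_burnin=50, n_chains=2, seed=42)
        a = run_gibbs(sim_dataset, config=cfg)
        b = run_gibbs(sim_dataset, config=cfg)
        for name in ("alpha", "beta", "gamma", "sigma", "C_draws"):
            assert np.array_equal(getattr(a, name), getattr(b, name))

    def test_recovers_true_effect_curve(self, sim_dataset):
        cfg = ChainConfig(n_iterations=4000, n_burnin=1000, n_chains=2, seed=3)
        chains = run_gibbs(sim_dataset, config=cfg)
        draws = chains.flat("beta")
        post_mean = draws.mean(axis=0)
        post_sd = draws.std(axis=0, ddof=1)
        assert (np.abs(post_mean - [10, 8, 6, 4, 2]) < 3 * post_sd).all()

    def test_no_contamination_reduces_to_arm_regression(self):
        # if every control stays untreated the latent structure is
        # degenerate and beta is the per-visit arm contrast
        cfg = SimConfig(n=400, base_seed=17, gamma_true=(0, 0, 0, 0, 0, 1))
        ds = generate_dataset(cfg, 0)
        chains = run_gibbs(ds, config=ChainConfig(n_iterations=2500,
                                                  n_burnin=500, n_chains=2,
                                                  seed=9))
        from longcace.moments import itt_differences

        post = chains.flat("beta").mean(axis=0)
        sd = chains.flat("beta").std(axis=0, ddof=1)
        assert np.abs(post - itt_differences(ds)).max() < 3 * sd.max()

    def test_missing_outcomes_imputed_and_stored(self):
        cfg = SimConfig(n=200, base_seed=23, missingness_rate=0.15)
        ds = generate_dataset(cfg, 0)
        assert 0 < ds.missing_mask.sum()
        chains = run_gibbs(ds, config=ChainConfig(n_iterations=300, n_burnin=100,
                                                  n_chains=2, seed=1))
        assert chains.missing_draws.shape[-1] == ds.missing_mask.sum()
        assert np.isfinite(chains.missing_draws).all()
        assert np.isfinite(chains.flat("beta")).all()

    def test_sigma_draws_positive_definite_gamma_on_simplex(self, sim_dataset):
        chains = run_gibbs(sim_dataset,
                           config=ChainConfig(n_iterations=200, n_burnin=50,
                                              n_chains=2, seed=11))
        sig = chains.flat("sigma")
        assert all(np.all(np.linalg.eigvalsh(S) > 0) for S in sig[::10])
        g = chains.flat("gamma")
        assert np.allclose(g.sum(axis=1), 1.0, atol=1e-10) and (g >= 0).all()


class TestGelmanRubin:
    def test_identical_chains_give_one(self, rng):
        x = rng.normal(size=1000)
        assert gelman_rubin(np.stack([x, x])) == pytest.approx(1.0, abs=1e-3)

    def test_independent_same_distribution_near_one(self, rng):
        chains = rng.normal(size=(4, 5000))
        assert gelman_rubin(chains) == pytest.approx(1.0, abs=0.02)

    def test_constant_chains_at_different_values_diverge(self):
        chains = np.array([[2.0] * 100, [3.0] * 100])
        assert gelman_rubin(chains) == np.inf

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.ones((1, 100)))

    def test_separated_chains_flagged(self, rng):
        chains = np.stack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
        assert gelman_rubin(chains) > 2.0
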