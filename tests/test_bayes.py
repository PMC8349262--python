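import numpy as np
import pytest

from kwstress import (
    McmcConfig,
    ModelParams,
    PosteriorSample,
    PriorSpec,
    Thresholds,
    TwoSampleData,
    gibbs_beta,
    kw_sample,
    log_likelihood,
    log_posterior,
    mh_alpha,
    posterior_summary,
    sample_posterior,
)
from kwstress.bayes import _log_cond_alpha

from conftest import THETA_1, THRESH, TRUE_R1, random_theta

VAGUE = PriorSpec()  # a_i = b_i = 0.1


class TestLogPosterior:
    def test_decomposes_into_likelihood_and_prior(self, rng, small_data):
        """logπ(θ)−logπ(θ′) = Δloglik + Δlogprior, computed independently."""

        def log_prior(theta):
            return (
                (VAGUE.a1 - 1) * np.log(theta.alpha)
                - VAGUE.b1 * theta.alpha
                + (VAGUE.a2 - 1) * np.log(theta.beta1)
                - VAGUE.b2 * theta.beta1
                + (VAGUE.a3 - 1) * np.log(theta.beta2)
                - VAGUE.b3 * theta.beta2
            )

        for _ in range(10):
            t1, t2 = random_theta(rng), random_theta(rng)
            lhs = log_posterior(t1, small_data, VAGUE) - log_posterior(t2, small_data, VAGUE)
            rhs = (
                log_likelihood(t1, small_data)
                - log_likelihood(t2, small_data)
                + log_prior(t1)
                - log_prior(t2)
            )
            assert lhs == pytest.approx(rhs, abs=1e-10)

    def test_flat_prior_map_approaches_mle(self, scenario1_data):
        from kwstress import fit_mle

        nearly_flat = PriorSpec(1.0, 1e-8, 1.0, 1e-8, 1.0, 1e-8)
        fit = fit_mle(scenario1_data)
        grid = np.linspace(0.8, 1.2, 81)
        lp = [
            log_posterior(
                ModelParams(fit.alpha * g, fit.beta1, fit.beta2), scenario1_data, nearly_flat
            )
            for g in grid
        ]
        assert abs(grid[int(np.argmax(lp))] - 1.0) < 0.01

    def test_improper_prior_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec(a1=1.0, b1=0.0)


class TestGibbsBeta:
    def test_moments_match_gamma_conditional(self, small_data):
        """Draws follow Gamma(a₂+n, b₂−lxx) exactly: check mean and variance."""
        alpha = 4.0
        rng = np.random.default_rng(8)
        draws = np.array([gibbs_beta(alpha, small_data, VAGUE, rng) for _ in range(100_000)])
        for col, (shape, rate) in enumerate(
            [
                (VAGUE.a2 + small_data.n, VAGUE.b2 - small_data.lxx(alpha)),
                (VAGUE.a3 + small_data.m, VAGUE.b3 - small_data.lyy(alpha)),
            ]
        ):
            mean, var = shape / rate, shape / rate**2
            se_mean = np.sqrt(var / draws.shape[0])
            assert abs(draws[:, col].mean() - mean) < 3 * se_mean
            assert draws[:, col].var(ddof=1) == pytest.approx(var, rel=0.05)
        assert np.all(draws > 0)

    def test_flat_prior_recovers_profile_mle(self, small_data):
        """With a_2, b_2 → 0 the conditional mean is −n/lxx, the profile MLE."""
        alpha = 3.0
        tiny = PriorSpec(0.1, 0.1, 1e-8, 1e-8, 1e-8, 1e-8)
        rng = np.random.default_rng(9)
        draws = np.array([gibbs_beta(alpha, small_data, tiny, rng) for _ in range(50_000)])
        from kwstress import profile_betas

        b1_star, b2_star = profile_betas(alpha, small_data)
        assert draws[:, 0].mean() == pytest.approx(b1_star, rel=0.02)
        assert draws[:, 1].mean() == pytest.approx(b2_star, rel=0.02)


class TestMhAlpha:
    def test_vanishing_proposal_accepts_everything(self, small_data):
        rng = np.random.default_rng(10)
        acc = [
            mh_alpha(3.0, 2.0, 2.0, small_data, VAGUE, 1e-8, rng)[1] for _ in range(200)
        ]
        assert np.mean(acc) > 0.99

    def test_invariant_density_of_alpha_conditional(self):
        """Long MH chain vs the grid-normalised exact conditional (KS check)."""
        d = TwoSampleData(
            kw_sample(10, THETA_1.x_params, seed=61),
            kw_sample(10, THETA_1.y_params, seed=62),
        )
        beta1, beta2 = 3.4, 3.1
        rng = np.random.default_rng(63)
        a = 4.0
        chain = np.empty(40_000)
        for i in range(chain.size):
            a, _ = mh_alpha(a, beta1, beta2, d, VAGUE, 0.5, rng)
            chain[i] = a
        chain = chain[2000::4]  # thin to reduce autocorrelation

        grid = np.linspace(1e-3, 20.0, 4001)
        logpdf = np.array([_log_cond_alpha(g, beta1, beta2, d, VAGUE) for g in grid])
        pdf = np.exp(logpdf - logpdf.max())
        cdf = np.cumsum(pdf)
        cdf /= cdf[-1]
        emp = np.searchsorted(np.sort(chain), grid) / chain.size
        # Kolmogorov-Smirnov distance between chain and target
        assert np.max(np.abs(emp - cdf)) < 0.03

    def test_positive_current_required(self, small_data):
        with pytest.raises(ValueError):
            mh_alpha(-1.0, 2.0, 2.0, small_data, VAGUE, 0.3, 0)


class TestSamplePosterior:
    def test_reproducible(self, small_data):
        cfg = McmcConfig(n_iter=800, burn_in=200, seed=5)
        a = sample_posterior(small_data, VAGUE, THRESH, cfg)
        b = sample_posterior(small_data, VAGUE, THRESH, cfg)
        assert np.array_equal(a.draws, b.draws)
        assert a.acceptance_rate == b.acceptance_rate

    def test_posterior_concentrates_at_truth(self, scenario1_data):
        cfg = McmcConfig(n_iter=4000, burn_in=1000, seed=6)
        ps = sample_posterior(scenario1_data, VAGUE, THRESH, cfg)
        post_sd = ps.r_draws.std(ddof=1)
        assert abs(ps.r_draws.mean() - TRUE_R1) < 3 * post_sd
        assert 0.05 < ps.acceptance_rate < 0.9

    def test_posterior_sd_shrinks_with_n(self):
        sds = []
        for n, seed in ((20, 71), (100, 72)):
            d = TwoSampleData(
                kw_sample(n, THETA_1.x_params, seed=seed),
                kw_sample(n, THETA_1.y_params, seed=seed + 10),
            )
            ps = sample_posterior(d, VAGUE, THRESH, McmcConfig(n_iter=3000, burn_in=600, seed=7))
            sds.append(ps.r_draws.std(ddof=1))
        assert sds[1] < sds[0]

    def test_successive_conditional_simulator_preserves_prior(self):
        """Joint-chain validation: alternating data-draw and one posterior sweep
        leaves the prior invariant, so the α margin must keep the prior mean."""
        prior = PriorSpec(4.0, 4.0, 4.0, 4.0, 4.0, 4.0)  # mean 1, sd 0.5 each
        rng = np.random.default_rng(90)
        alpha, beta1, beta2 = 1.0, 1.0, 1.0
        keep = []
        for i in range(6000):
            theta = ModelParams(alpha, beta1, beta2)
            x = kw_sample(5, theta.x_params, rng)
            y = kw_sample(5, theta.y_params, rng)
            d = TwoSampleData(x, y)
            alpha, _ = mh_alpha(alpha, beta1, beta2, d, prior, 0.6, rng)
            beta1, beta2 = gibbs_beta(alpha, d, prior, rng)
            if i >= 500:
                keep.append(alpha)
        keep = np.array(keep)
        # crude batch-means standard error to allow for autocorrelation
        bm = keep[: 50 * (keep.size // 50)].reshape(-1, 50).mean(axis=1)
        se = bm.std(ddof=1) / np.sqrt(bm.size)
        assert abs(keep.mean() - 1.0) < 4 * se


class TestPosteriorSummary:
    def test_constant_chain(self):
        ps = PosteriorSample(
            draws=np.ones((100, 3)), r_draws=np.full(100, 0.5),
            acceptance_rate=0.4, proposal_sd=0.3,
        )
        s = posterior_summary(ps, 0.95)
        assert s.point == 0.5 and s.lower == s.upper == 0.5

    def test_uniform_draws_quantiles(self, rng):
        r = rng.random(200_000)
        ps = PosteriorSample(
            draws=np.ones((r.size, 3)), r_draws=r, acceptance_rate=0.4, proposal_sd=0.3
        )
        s = posterior_summary(ps, 0.95)
        assert s.lower == pytest.approx(0.025, abs=0.005)
        assert s.upper == pytest.approx(0.975, abs=0.005)

    def test_interval_contains_median(self, rng):
        r = rng.beta(2, 5, 5000)
        ps = PosteriorSample(
            draws=np.ones((r.size, 3)), r_draws=r, acceptance_rate=0.4, proposal_sd=0.3
        )
        s = posterior_summary(ps, 0.6)
        med = np.median(r)
        assert s.lower <= med <= s.upper
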