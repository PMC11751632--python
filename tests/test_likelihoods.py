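"""Count likelihoods, KL, ELBO and importance-sampled marginal likelihood."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from convvae.likelihoods import (
    GaussianPosterior,
    elbo,
    importance_log_likelihood,
    kl_std_normal,
    nb_logpmf,
    poisson_logpmf,
    reparameterize,
    softmax_rates,
)


class TestSoftmaxRates:
    def test_uniform_logits(self):
        dec = softmax_rates(np.zeros((1, 4)), np.array([8.0]))
        assert np.allclose(dec.probabilities, 0.25)
        assert np.allclose(dec.rates, 2.0)

    def test_closed_form(self):
        dec = softmax_rates(np.array([[0.0, np.log(2)]]), np.array([1.0]))
        assert np.allclose(dec.probabilities, [[1 / 3, 2 / 3]])

    def test_shift_invariance_and_library_conservation(self):
        rng = np.random.default_rng(0)
        rho = rng.standard_normal((3, 2, 6))
        lib = rng.uniform(10, 100, size=(3, 2))
        dec = softmax_rates(rho, lib)
        dec_shift = softmax_rates(rho + 5.0, lib)
        assert np.allclose(dec.probabilities, dec_shift.probabilities)
        assert np.allclose(dec.probabilities.sum(axis=-1), 1.0, atol=1e-6)
        assert np.allclose(dec.rates.sum(axis=-1), lib, rtol=1e-6)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            softmax_rates(np.array([[np.inf, 0.0]]), np.array([1.0]))


class TestPoissonLogpmf:
    @pytest.mark.parametrize("x,lam,expected", [
        (0, 1.0, -1.0),
        (2, 2.0, np.log(2) - 2),
        (0, 0.0, 0.0),
    ])
    def test_values(self, x, lam, expected):
        assert np.isclose(poisson_logpmf(x, lam), expected)

    def test_zero_rate_positive_count(self):
        assert poisson_logpmf(3, 0.0) == -np.inf

    def test_matches_scipy_and_sums_to_one(self):
        xs = np.arange(0, 60)
        lp = poisson_logpmf(xs, 2.5)
        assert np.allclose(lp, stats.poisson.logpmf(xs, 2.5))
        assert np.isclose(np.exp(lp).sum(), 1.0, atol=1e-12)


class TestNbLogpmf:
    def test_zero_count_closed_form(self):
        theta, mu = 2.0, 3.0
        assert np.isclose(nb_logpmf(0, mu, theta), theta * np.log(theta / (theta + mu)))

    def test_geometric_special_case(self):
        assert np.isclose(nb_logpmf(1, 1.0, 1.0), np.log(0.25))

    def test_poisson_limit(self):
        assert abs(nb_logpmf(3, 2.0, 1e6) - poisson_logpmf(3, 2.0)) < 1e-4

    def test_matches_scipy_parameterization(self):
        # scipy nbinom: n = theta, p = theta / (theta + mu)
        xs = np.arange(0, 20)
        theta, mu = 1.7, 4.2
        assert np.allclose(nb_logpmf(xs, mu, theta),
                           stats.nbinom.logpmf(xs, theta, theta / (theta + mu)))


class TestKlStdNormal:
    def test_prior_posterior_gives_zero(self):
        post = GaussianPosterior(np.zeros((2, 3)), np.ones((2, 3)))
        assert np.allclose(kl_std_normal(post), 0.0)

    def test_unit_mean_closed_form(self):
        post = GaussianPosterior(np.ones((1, 1)), np.ones((1, 1)))
        assert np.isclose(kl_std_normal(post)[0], 0.5)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        post = GaussianPosterior(rng.normal(size=(4, 3)),
                                 rng.uniform(0.1, 3.0, size=(4, 3)))
        assert (kl_std_normal(post) >= 0).all()


class TestReparameterize:
    def test_zero_stdev_returns_mean(self):
        post = GaussianPosterior(np.full((2, 3), 1.5), np.full((2, 3), 1e-12))
        assert np.allclose(reparameterize(post, np.random.default_rng(0)), 1.5)

    def test_seeded_reproducibility(self):
        post = GaussianPosterior(np.zeros((2, 3)), np.ones((2, 3)))
        a = reparameterize(post, np.random.default_rng(5))
        b = reparameterize(post, np.random.default_rng(5))
        assert np.array_equal(a, b)

    def test_sample_mean_within_clt_band(self):
        n = 10 ** 5
        post = GaussianPosterior(np.full((n, 1), 2.0), np.full((n, 1), 3.0))
        z = reparameterize(post, np.random.default_rng(1))
        se = 3.0 / np.sqrt(n)
        assert abs(z.mean() - 2.0) < 4 * se


class TestElbo:
    def test_prior_posterior_reduces_to_reconstruction(self):
        x = np.array([[[1, 0]]], dtype=float)
        post = GaussianPosterior(np.zeros((1, 2)), np.ones((1, 2)))
        dec = softmax_rates(np.zeros((1, 1, 2)), np.array([[1.0]]))
        expected = poisson_logpmf(1, 0.5) + poisson_logpmf(0, 0.5)
        assert np.isclose(elbo(x, post, dec), expected)

    def test_hand_computed_value(self):
        # single cell, M=1, G=2, x=[1,0], w=[1/2,1/2], l=1, KL=0
        x = np.array([[[1, 0]]], dtype=float)
        post = GaussianPosterior(np.zeros((1, 1)), np.ones((1, 1)))
        dec = softmax_rates(np.zeros((1, 1, 2)), np.array([[1.0]]))
        assert np.isclose(elbo(x, post, dec), np.log(0.5) - 1.0)


class TestImportanceLogLikelihood:
    """Linear-Gaussian toy: x = z + eps, analytic marginal available."""

    @staticmethod
    def _toy(n=6, d=3, noise_sd=0.7, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, np.sqrt(1 + noise_sd ** 2), size=(n, d))
        # exact posterior: precision 1 + 1/s2, mean = x/s2 / precision
        prec = 1.0 + 1.0 / noise_sd ** 2
        post = GaussianPosterior(mean=(x / noise_sd ** 2) / prec,
                                 stdev=np.full((n, d), 1 / np.sqrt(prec)))

        def decode_fn(z):
            return stats.norm.logpdf(x, loc=z, scale=noise_sd).sum(axis=1)

        marginal = stats.norm.logpdf(x, scale=np.sqrt(1 + noise_sd ** 2)).sum(axis=1)
        return x, post, decode_fn, marginal

    def test_single_sample_identity(self):
        x, post, decode_fn, _ = self._toy()
        rng = np.random.default_rng(3)
        z = post.mean + post.stdev * rng.standard_normal(post.mean.shape)
        expected = (decode_fn(z)
                    + stats.norm.logpdf(z).sum(axis=1)
                    - stats.norm.logpdf(z, post.mean, post.stdev).sum(axis=1))
        got = importance_log_likelihood(x, post, decode_fn, n_samples=1, seed=3,
                                        return_per_cell=True)
        assert np.allclose(got, expected)

    def test_matches_analytic_marginal(self):
        x, post, decode_fn, marginal = self._toy()
        # exact posterior as proposal: the weights are constant, any Ns is exact
        got = importance_log_likelihood(x, post, decode_fn, n_samples=100, seed=0,
                                        return_per_cell=True)
        assert np.allclose(got, marginal, atol=1e-8)

    def test_approximate_posterior_converges(self):
        x, post, decode_fn, marginal = self._toy()
        rough = GaussianPosterior(post.mean * 0.8, post.stdev * 1.5)
        got = importance_log_likelihood(x, rough, decode_fn, n_samples=10_000, seed=1)
        assert abs(got - marginal.mean()) < 0.02

    def test_estimate_nondecreasing_in_ns(self):
        x, post, decode_fn, _ = self._toy(seed=4)
        rough = GaussianPosterior(post.mean * 0.5, post.stdev * 2.0)
        means = []
        for ns in (1, 10, 100):
            reps = [importance_log_likelihood(x, rough, decode_fn, n_samples=ns,
                                              seed=s) for s in range(30)]
            means.append(np.mean(reps))
        assert means[0] <= means[1] <= means[2]

    def test_elbo_lower_bounds_marginal(self):
        x, post, decode_fn, marginal = self._toy(seed=2)
        rough = GaussianPosterior(post.mean * 0.7, post.stdev * 1.3)
        rng = np.random.default_rng(0)
        elbos = []
        for _ in range(200):
            z = rough.mean + rough.stdev * rng.standard_normal(rough.mean.shape)
            elbos.append(np.mean(decode_fn(z)) - np.mean(kl_std_normal(rough)))
        assert np.mean(elbos) <= marginal.mean()

    def test_requires_positive_samples(self):
        x, post, decode_fn, _ = self._toy()
        with pytest.raises(ValueError):
            importance_log_likelihood(x, post, decode_fn, n_samples=0)
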