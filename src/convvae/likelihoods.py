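"""Probabilistic machinery shared by the VAE models.

Generative model per cell i, modality m, bin g:

    rho_i  = decoder(z_i, b_i)                 (logits, one channel per modality)
    w_mgi  = softmax_g(rho_mgi)                (softmax over bins within a modality)
    lam_mgi = w_mgi * l_mi                     (library size l_mi scales rates)
    x_mgi  ~ Poisson(lam_mgi)   or   NB(mean lam_mgi, dispersion theta_mg)

with z ~ N(0, I_D) and a diagonal-Gaussian variational posterior. The NB
dispersion is one positive value per (modality, bin) feature, shared
across cells. All likelihood sums accumulate in float64.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "GaussianPosterior",
    "DecodedRates",
    "softmax_rates",
    "poisson_logpmf",
    "nb_logpmf",
    "kl_std_normal",
    "reparameterize",
    "elbo",
    "importance_log_likelihood",
]


@dataclass(frozen=True)
class GaussianPosterior:
    """Diagonal Gaussian q(z | X, b): per-cell mean and stdev (N x D)."""

    mean: np.ndarray
    stdev: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=np.float64))
        object.__setattr__(self, "stdev", np.asarray(self.stdev, dtype=np.float64))
        if self.mean.shape != self.stdev.shape:
            raise ValueError("mean/stdev shape mismatch")
        if (self.stdev <= 0).any():
            raise ValueError("stdev must be positive")


@dataclass(frozen=True)
class DecodedRates:
    """Decoder output: logits rho, bin probabilities w, Poisson rates lam."""

    logits: np.ndarray        # (N, M, G)
    probabilities: np.ndarray  # (N, M, G); sums to 1 over bins per (cell, modality)
    rates: np.ndarray          # (N, M, G); w * l


def softmax_rates(rho: np.ndarray, lib: np.ndarray) -> DecodedRates:
    """Softmax over bins within each modality channel; scale by library size.

    ``rho`` is (..., M, G); ``lib`` is (..., M) and broadcasts over bins.
    """
    rho = np.asarray(rho, dtype=np.float64)
    if not np.isfinite(rho).all():
        raise ValueError("logits must be finite")
    shifted = rho - rho.max(axis=-1, keepdims=True)
    expd = np.exp(shifted)
    w = expd / expd.sum(axis=-1, keepdims=True)
    lam = w * np.asarray(lib, dtype=np.float64)[..., None]
    return DecodedRates(logits=rho, probabilities=w, rates=lam)


def poisson_logpmf(x, lam):
    """log Poisson pmf; by convention returns 0 at (x=0, lam=0), -inf if x>0."""
    x = np.asarray(x, dtype=np.float64)
    lam = np.asarray(lam, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = x * np.log(lam) - lam - gammaln(x + 1)
    zero = lam == 0
    if np.any(zero):
        out = np.where(zero & (x == 0), 0.0, out)
        out = np.where(zero & (x > 0), -np.inf, out)
    return out


def nb_logpmf(x, mean, dispersion):
    """log NB pmf, mean/dispersion parameterization (theta = inverse overdispersion).

    ln Gamma(x+theta) - ln Gamma(theta) - ln x! + theta ln(theta/(theta+mu))
    + x ln(mu/(theta+mu)); Var = mu + mu^2/theta, so theta -> inf recovers Poisson.
    """
    x = np.asarray(x, dtype=np.float64)
    mu = np.asarray(mean, dtype=np.float64)
    theta = np.asarray(dispersion, dtype=np.float64)
    log_theta_mu = np.log(theta + mu)
    with np.errstate(divide="ignore", invalid="ignore"):
        xlog = np.where(x > 0, x * (np.log(mu) - log_theta_mu), 0.0)
    return (gammaln(x + theta) - gammaln(theta) - gammaln(x + 1)
            + theta * (np.log(theta) - log_theta_mu) + xlog)


def kl_std_normal(posterior: GaussianPosterior) -> np.ndarray:
    """KL(q || N(0, I)) per cell: sum_d 0.5 (mu^2 + sigma^2 - 1 - ln sigma^2)."""
    mu, sd = posterior.mean, posterior.stdev
    return 0.5 * np.sum(mu ** 2 + sd ** 2 - 1.0 - 2.0 * np.log(sd), axis=-1)


def reparameterize(posterior: GaussianPosterior, rng: np.random.Generator) -> np.ndarray:
    """z = mu + sigma * eps, eps ~ N(0, I) from the provided generator."""
    eps = rng.standard_normal(posterior.mean.shape)
    return posterior.mean + posterior.stdev * eps


def _recon_loglik(x, decoded: DecodedRates, likelihood: str, dispersion=None):
    """Sum over modalities and bins of log p(x | z, b), per cell."""
    if likelihood == "poisson":
        lp = poisson_logpmf(x, decoded.rates)
    elif likelihood == "nb":
        if dispersion is None:
            raise ValueError("nb likelihood requires dispersion parameters")
        lam = decoded.rates
        lp = np.where(lam > 0, nb_logpmf(x, np.maximum(lam, 1e-300), dispersion),
                      poisson_logpmf(x, lam))
    else:
        raise ValueError(f"unknown likelihood {likelihood!r}")
    return lp.sum(axis=(-2, -1), dtype=np.float64)


def elbo(x, posterior: GaussianPosterior, decoded: DecodedRates,
         likelihood: str = "poisson", dispersion=None) -> float:
    """Single-sample ELBO estimate, mean over cells.

    Reconstruction is summed over modalities and bins (the channels are
    conditionally independent given z and b); KL is against N(0, I).
    """
    recon = _recon_loglik(np.asarray(x, dtype=np.float64), decoded, likelihood, dispersion)
    kl = kl_std_normal(posterior)
    return float(np.mean(recon - kl))


def _std_normal_logpdf(z):
    return -0.5 * (z ** 2 + np.log(2 * np.pi)).sum(axis=-1)


def _gaussian_logpdf(z, mean, stdev):
    return -0.5 * (((z - mean) / stdev) ** 2 + np.log(2 * np.pi)
                   + 2 * np.log(stdev)).sum(axis=-1)


def importance_log_likelihood(x, posterior: GaussianPosterior, decode_fn,
                              n_samples: int = 100, seed: int = 0,
                              return_per_cell: bool = False):
    """Importance-sampled marginal log-likelihood log p(X | b).

    Per cell: log (1/Ns) sum_s p(X | z_s, b) p(z_s) / q(z_s | X, b), with
    z_s drawn from the posterior and the average taken with log-sum-exp.
    ``decode_fn(z) -> (N,) log p(X | z, b)`` evaluates the conditional
    data log-likelihood at one latent draw per cell.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    n = posterior.mean.shape[0]
    log_w = np.empty((n_samples, n))
    for s in range(n_samples):
        z = reparameterize(posterior, rng)
        log_w[s] = (np.asarray(decode_fn(z), dtype=np.float64)
                    + _std_normal_logpdf(z) - _gaussian_logpdf(z, posterior.mean, posterior.stdev))
    per_cell = logsumexp(log_w, axis=0) - np.log(n_samples)
    if return_per_cell:
        return per_cell
    return float(per_cell.mean())
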