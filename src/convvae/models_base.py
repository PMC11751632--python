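"""Shared training machinery for the VAE estimators.

Both architectures optimize the negative ELBO with Adam on mini-batches:
the encoder consumes log1p-transformed channels, the decoder conditions
on the batch one-hot and emits per-modality softmax bin probabilities
scaled by the observed library sizes. The gradient of the reconstruction
term with respect to the decoder logits has the closed form

    d(-log p)/d rho = l * w * (a - sum_g w a),   a = d(-log p)/d lambda,

which for the Poisson likelihood collapses to ``w * l - x``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma

from .data import MultimodalTensor, library_sizes, log1p_channels
from .likelihoods import (
    DecodedRates,
    GaussianPosterior,
    elbo,
    importance_log_likelihood,
    kl_std_normal,
    softmax_rates,
)

LOGVAR_CLIP = 15.0


@dataclass
class TrainConfig:
    """Optimization settings: Adam, mini-batch 128, learning rate 1e-3."""

    batch_size: int = 128
    learning_rate: float = 1e-3
    epochs: int = 50
    seed: int = 0

    def __post_init__(self):
        if min(self.batch_size, self.epochs) <= 0 or self.learning_rate <= 0:
            raise ValueError("TrainConfig values must be positive")


@dataclass(frozen=True)
class LayerSummary:
    name: str
    input_shape: tuple
    output_shape: tuple
    n_params: int


def as_tensor(X) -> MultimodalTensor:
    if isinstance(X, MultimodalTensor):
        return X
    raise TypeError("expected a MultimodalTensor; build one from a dense array "
                    "with convvae.data.MultimodalTensor")


def poisson_dnll_drho(x, w, lib):
    """Gradient of the Poisson NLL wrt logits: w * l - x (per cell sum form)."""
    return w * lib[..., None] - x


def nb_dnll(x, lam, theta):
    """Gradients of the NB NLL wrt rate lambda and log-dispersion.

    Returns (a, dlogtheta) where a = d(-log p)/d lambda elementwise and
    dlogtheta is summed over cells (theta is shared across cells).
    """
    lam = np.maximum(lam, 1e-300)
    a = (theta + x) / (theta + lam) - np.where(x > 0, x / lam, 0.0)
    dlp_dtheta = (digamma(x + theta) - digamma(theta) + np.log(theta) + 1.0
                  - np.log(theta + lam) - (theta + x) / (theta + lam))
    dlogtheta = -(theta * dlp_dtheta).sum(axis=0)
    return a, dlogtheta


def rho_grad_from_rate_grad(a, w, lib):
    """Chain rule through lambda = l * softmax(rho): l*w*(a - sum w a)."""
    inner = (w * a).sum(axis=-1, keepdims=True)
    return lib[..., None] * w * (a - inner)


class VaeCore:
    """Encoder/decoder pair with the reparameterized Gaussian bottleneck.

    Subclass hooks: ``_encode(xlog, onehot, training) -> (N, 2D)`` raw
    output, ``_encode_backward(dout)``, ``_decode(z, onehot, training) ->
    (N, M, G) logits``, ``_decode_backward(drho) -> dz``, and
    ``param_handles()`` listing (layer, name) pairs for the optimizer.
    """

    latent_dim: int
    likelihood: str

    def posterior(self, xlog, onehot, training):
        raw = self._encode(xlog, onehot, training)
        d = self.latent_dim
        mu, logvar = raw[:, :d], np.clip(raw[:, d:], -LOGVAR_CLIP, LOGVAR_CLIP)
        return mu, logvar

    def decoded(self, z, onehot, lib, training):
        rho = self._decode(z, onehot, training)
        return softmax_rates(rho, lib)

    def loss_and_grads(self, x, lib, onehot, rng):
        """One forward/backward pass; returns per-batch mean negative ELBO."""
        n = x.shape[0]
        xlog = np.log1p(x)
        mu, logvar = self.posterior(xlog, onehot, training=True)
        sigma = np.exp(0.5 * logvar)
        eps = rng.standard_normal(mu.shape)
        z = mu + sigma * eps
        dec = self.decoded(z, onehot, lib, training=True)

        if self.likelihood == "poisson":
            drho = poisson_dnll_drho(x, dec.probabilities, lib) / n
            nll = -(x * np.log(np.maximum(dec.rates, 1e-300))
                    - dec.rates).sum(axis=(1, 2))
        else:
            theta = np.exp(self.log_theta.params["log_theta"])
            a, dlogtheta = nb_dnll(x, dec.rates, theta)
            drho = rho_grad_from_rate_grad(a, dec.probabilities, lib) / n
            self.log_theta.grads["log_theta"] += dlogtheta / n
            from .likelihoods import nb_logpmf
            nll = -nb_logpmf(x, np.maximum(dec.rates, 1e-300), theta).sum(axis=(1, 2))
        kl = 0.5 * np.sum(mu ** 2 + np.exp(logvar) - 1.0 - logvar, axis=1)
        loss = float((nll + kl).mean())

        dz = self._decode_backward(drho)
        dmu = dz + mu / n
        dlogvar = dz * (0.5 * sigma * eps) + 0.5 * (np.exp(logvar) - 1.0) / n
        self._encode_backward(np.concatenate([dmu, dlogvar], axis=1))
        return loss

    def eval_posterior(self, x, onehot) -> GaussianPosterior:
        mu, logvar = self.posterior(np.log1p(x), onehot, training=False)
        return GaussianPosterior(mean=mu, stdev=np.exp(0.5 * logvar))

    def eval_elbo(self, x, lib, onehot, seed=0) -> float:
        post = self.eval_posterior(x, onehot)
        rng = np.random.default_rng(seed)
        z = post.mean + post.stdev * rng.standard_normal(post.mean.shape)
        dec = self.decoded(z, onehot, lib, training=False)
        disp = None
        if self.likelihood == "nb":
            disp = np.exp(self.log_theta.params["log_theta"])
        return elbo(x, post, dec, likelihood=self.likelihood, dispersion=disp)


def minibatch_train(core: VaeCore, x_dense, lib, onehot, cfg: TrainConfig,
                    optimizer) -> list[float]:
    """Seeded mini-batch loop; returns the per-epoch mean loss history."""
    n = x_dense.shape[0]
    shuffle_rng = np.random.default_rng(cfg.seed + 1)
    noise_rng = np.random.default_rng(cfg.seed + 2)
    history = []
    for epoch in range(cfg.epochs):
        order = shuffle_rng.permutation(n)
        losses, weights = [], []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            optimizer.zero_grad()
            loss = core.loss_and_grads(x_dense[idx], lib[idx], onehot[idx], noise_rng)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch offset {start}; "
                    "consider lowering the learning rate")
            optimizer.step()
            losses.append(loss)
            weights.append(len(idx))
        history.append(float(np.average(losses, weights=weights)))
    return history


def model_log_likelihood(core: VaeCore, x, lib, onehot, n_samples=100, seed=0,
                         return_per_cell=False):
    """Importance-sampled marginal log-likelihood under the trained model."""
    post = core.eval_posterior(x, onehot)
    disp = np.exp(core.log_theta.params["log_theta"]) if core.likelihood == "nb" else None

    def decode_fn(z):
        dec = core.decoded(z, onehot, lib, training=False)
        from .likelihoods import _recon_loglik
        return _recon_loglik(x, dec, core.likelihood, disp)

    return importance_log_likelihood(x, post, decode_fn, n_samples=n_samples,
                                     seed=seed, return_per_cell=return_per_cell)


def prepare_inputs(tensor: MultimodalTensor, conditional: bool):
    """Dense counts, library sizes, and the batch design used in training."""
    x = tensor.to_dense()
    lib = library_sizes(tensor).values.astype(np.float64)
    if conditional:
        design = tensor.batch_design()
        onehot, levels = design.one_hot, design.level_names
    else:
        onehot, levels = np.zeros((tensor.n_cells, 0)), []
    zero_cells = int((lib.sum(axis=1) == 0).sum())
    if zero_cells:
        import logging
        logging.getLogger(__name__).warning("%d cells have zero counts in "
                                            "every modality", zero_cells)
    return x, lib, onehot, levels
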