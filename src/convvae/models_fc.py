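"""Product-of-experts fully connected multimodal VAE (the FC baseline).

One expert (encoder + decoder pair) per modality. Each encoder maps the
log1p counts of its modality, concatenated with the batch one-hot,
through L hidden FC blocks (BatchNorm + ReLU + Dropout) to a diagonal
Gaussian (mu_m, V_m). The experts are fused by a product of Gaussians —
precisions add, means are precision-weighted — together with a standard
normal prior pseudo-expert. Each decoder maps (z, b) through L hidden
blocks and a final linear layer to G bin logits; softmax times the
modality library size gives the rates, exactly as in the conv model so
likelihoods are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import nn
from .likelihoods import GaussianPosterior
from .models_base import (
    LOGVAR_CLIP,
    LayerSummary,
    TrainConfig,
    VaeCore,
    as_tensor,
    minibatch_train,
    model_log_likelihood,
    prepare_inputs,
)

__all__ = [
    "ExpertPosterior",
    "poe_fuse",
    "FcVaeSpec",
    "PoEFcVAE",
    "build_fc_vae",
    "fit",
    "embed",
]


@dataclass(frozen=True)
class ExpertPosterior:
    """Per-modality Gaussian expert: mean and variance, (N x D) each."""

    mean: np.ndarray
    variance: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=np.float64))
        object.__setattr__(self, "variance", np.asarray(self.variance, dtype=np.float64))
        if (self.variance <= 0).any():
            raise ValueError("expert variance must be positive")

    @property
    def precision(self) -> np.ndarray:
        return 1.0 / self.variance


def poe_fuse(experts, include_prior: bool = True) -> GaussianPosterior:
    """Fuse Gaussian experts: Sigma = (sum T_m)^-1, mu = (sum mu_m T_m) Sigma.

    With ``include_prior`` a pseudo-expert with mean 0 and variance 1
    joins the sums, realizing the prior factors of the joint posterior.
    """
    if not experts:
        raise ValueError("need at least one expert")
    t_sum = np.ones_like(experts[0].mean) if include_prior else np.zeros_like(experts[0].mean)
    weighted = np.zeros_like(experts[0].mean)
    for e in experts:
        t_sum = t_sum + e.precision
        weighted = weighted + e.mean * e.precision
    variance = 1.0 / t_sum
    return GaussianPosterior(mean=weighted * variance, stdev=np.sqrt(variance))


@dataclass
class FcVaeSpec:
    """Declarative PoE FC-VAE architecture description."""

    n_modalities: int
    n_bins: int
    n_batches: int
    latent_dim: int = 30
    n_hidden_layers_per_expert: int = 1
    hidden_fc: int = 128
    dropout: float = 0.2
    likelihood: str = "poisson"
    include_prior_expert: bool = True

    def __post_init__(self):
        if not 1 <= self.n_hidden_layers_per_expert <= 3:
            raise ValueError("n_hidden_layers_per_expert must be 1-3")


class _FcCore(VaeCore):
    def __init__(self, spec: FcVaeSpec, rng: np.random.Generator):
        self.spec = spec
        self.latent_dim = spec.latent_dim
        self.likelihood = spec.likelihood
        L, h = spec.n_hidden_layers_per_expert, spec.hidden_fc
        self.encoders, self.decoders = [], []
        for _ in range(spec.n_modalities):
            enc = []
            width = spec.n_bins + spec.n_batches
            for _ in range(L):
                enc += [nn.Linear(width, h, rng), nn.BatchNorm1d(h), nn.ReLU(),
                        nn.Dropout(spec.dropout, rng)]
                width = h
            enc.append(nn.Linear(h, 2 * spec.latent_dim, rng))
            self.encoders.append(nn.Sequential(*enc))
            dec = []
            width = spec.latent_dim + spec.n_batches
            for _ in range(L):
                dec += [nn.Linear(width, h, rng), nn.BatchNorm1d(h), nn.ReLU(),
                        nn.Dropout(spec.dropout, rng)]
                width = h
            dec.append(nn.Linear(h, spec.n_bins, rng))
            self.decoders.append(nn.Sequential(*dec))
        if spec.likelihood == "nb":
            self.log_theta = nn.Layer()
            self.log_theta.params["log_theta"] = np.zeros((spec.n_modalities, spec.n_bins))
            self.log_theta.zero_grad()

    # -- forward/backward hooks ------------------------------------------
    def _encode(self, xlog, onehot, training):
        d = self.latent_dim
        mus, logvars, masks = [], [], []
        for m, enc in enumerate(self.encoders):
            raw = enc.forward(np.concatenate([xlog[:, m, :], onehot], axis=1),
                              training=training)
            lv = raw[:, d:]
            masks.append((lv > -LOGVAR_CLIP) & (lv < LOGVAR_CLIP))
            mus.append(raw[:, :d])
            logvars.append(np.clip(lv, -LOGVAR_CLIP, LOGVAR_CLIP))
        t = np.stack([np.exp(-lv) for lv in logvars])         # (M, N, D) precisions
        t_sum = t.sum(axis=0)
        if self.spec.include_prior_expert:
            t_sum = t_sum + 1.0
        mu_stack = np.stack(mus)
        mu = (mu_stack * t).sum(axis=0) / t_sum
        self._poe_cache = (mu_stack, t, t_sum, mu, masks)
        return np.concatenate([mu, -np.log(t_sum)], axis=1)

    def _encode_backward(self, dout):
        d = self.latent_dim
        dmu_f, dlogvar_f = dout[:, :d], dout[:, d:]
        mu_stack, t, t_sum, mu, masks = self._poe_cache
        d_tsum = -dlogvar_f / t_sum - dmu_f * mu / t_sum
        d_s = dmu_f / t_sum                       # wrt sum_m mu_m T_m
        for m, enc in enumerate(self.encoders):
            dmu_m = d_s * t[m]
            dt_m = d_s * mu_stack[m] + d_tsum
            dlogvar_m = -dt_m * t[m] * masks[m]
            enc.backward(np.concatenate([dmu_m, dlogvar_m], axis=1))

    def _decode(self, z, onehot, training):
        zin = np.concatenate([z, onehot], axis=1)
        return np.stack([dec.forward(zin, training=training)
                         for dec in self.decoders], axis=1)

    def _decode_backward(self, drho):
        d = self.latent_dim
        dz = 0.0
        for m, dec in enumerate(self.decoders):
            dz = dz + dec.backward(drho[:, m, :])[:, :d]
        return dz

    def param_handles(self):
        handles = []
        for seq in self.encoders + self.decoders:
            handles += [(layer, name) for layer, name, _, _ in seq.param_items()]
        if self.likelihood == "nb":
            handles.append((self.log_theta, "log_theta"))
        return handles

    def layer_summaries(self) -> list[LayerSummary]:
        rows = []
        for m, (enc, dec) in enumerate(zip(self.encoders, self.decoders)):
            for j, layer in enumerate(enc.layers):
                if layer.n_params:
                    rows.append(LayerSummary(f"expert{m}.encoder.{j}."
                                             f"{type(layer).__name__}",
                                             (), (), layer.n_params))
            for j, layer in enumerate(dec.layers):
                if layer.n_params:
                    rows.append(LayerSummary(f"expert{m}.decoder.{j}."
                                             f"{type(layer).__name__}",
                                             (), (), layer.n_params))
        if self.likelihood == "nb":
            rows.append(LayerSummary("nb.log_theta", (), (), self.log_theta.n_params))
        return rows


def build_fc_vae(spec: FcVaeSpec, seed: int = 0) -> _FcCore:
    return _FcCore(spec, np.random.default_rng(seed))


class PoEFcVAE(TransformerMixin, BaseEstimator):
    """Scikit-learn style estimator for the PoE fully connected VAE.

    See :class:`~convvae.models_conv.ConvNetVAE` for the shared interface;
    ``transform`` returns the fused posterior mean per cell.
    """

    def __init__(self, n_hidden_layers=1, hidden_fc=128, latent_dim=30,
                 dropout=0.2, likelihood="poisson", include_prior_expert=True,
                 conditional=True, batch_size=128, learning_rate=1e-3,
                 epochs=50, seed=0):
        self.n_hidden_layers = n_hidden_layers
        self.hidden_fc = hidden_fc
        self.latent_dim = latent_dim
        self.dropout = dropout
        self.likelihood = likelihood
        self.include_prior_expert = include_prior_expert
        self.conditional = conditional
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.seed = seed

    def fit(self, X, y=None):
        tensor = as_tensor(X)
        x, lib, onehot, levels = prepare_inputs(tensor, self.conditional)
        spec = FcVaeSpec(n_modalities=tensor.n_modalities, n_bins=tensor.n_bins,
                         n_batches=onehot.shape[1], latent_dim=self.latent_dim,
                         n_hidden_layers_per_expert=self.n_hidden_layers,
                         hidden_fc=self.hidden_fc, dropout=self.dropout,
                         likelihood=self.likelihood,
                         include_prior_expert=self.include_prior_expert)
        core = build_fc_vae(spec, seed=self.seed)
        cfg = TrainConfig(batch_size=self.batch_size, learning_rate=self.learning_rate,
                          epochs=self.epochs, seed=self.seed)
        optimizer = nn.Adam(core.param_handles(), lr=cfg.learning_rate)
        self.loss_history_ = minibatch_train(core, x, lib, onehot, cfg, optimizer)
        self.core_ = core
        self.spec_ = spec
        self.batch_levels_ = levels
        self.n_parameters_ = sum(r.n_params for r in core.layer_summaries())
        return self

    def _design(self, tensor):
        if not self.conditional:
            return np.zeros((tensor.n_cells, 0))
        unseen = set(tensor.batch_labels) - set(self.batch_levels_)
        if unseen:
            raise ValueError(f"batch levels {sorted(unseen)} were not seen in fit "
                             f"(training levels: {self.batch_levels_})")
        index = {b: j for j, b in enumerate(self.batch_levels_)}
        one_hot = np.zeros((tensor.n_cells, len(self.batch_levels_)))
        for i, b in enumerate(tensor.batch_labels):
            one_hot[i, index[b]] = 1.0
        return one_hot

    def transform(self, X):
        check_is_fitted(self, "core_")
        tensor = as_tensor(X)
        return self.core_.eval_posterior(tensor.to_dense(), self._design(tensor)).mean

    def score(self, X, y=None, seed: int = 0) -> float:
        check_is_fitted(self, "core_")
        tensor = as_tensor(X)
        x, lib, _, _ = prepare_inputs(tensor, self.conditional)
        return self.core_.eval_elbo(x, lib, self._design(tensor), seed=seed)

    def log_likelihood(self, X, n_samples: int = 100, seed: int = 0,
                       return_per_cell: bool = False):
        check_is_fitted(self, "core_")
        tensor = as_tensor(X)
        x, lib, _, _ = prepare_inputs(tensor, self.conditional)
        return model_log_likelihood(self.core_, x, lib, self._design(tensor),
                                    n_samples=n_samples, seed=seed,
                                    return_per_cell=return_per_cell)

    def layer_summary(self) -> list[LayerSummary]:
        check_is_fitted(self, "core_")
        return self.core_.layer_summaries()


def fit(model: PoEFcVAE, tensor, cfg: TrainConfig | None = None) -> PoEFcVAE:
    if cfg is not None:
        model.set_params(batch_size=cfg.batch_size, learning_rate=cfg.learning_rate,
                         epochs=cfg.epochs, seed=cfg.seed)
    return model.fit(tensor)


def embed(model: PoEFcVAE, tensor) -> np.ndarray:
    return model.transform(tensor)
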