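"""ConvNet-VAE: a 1D-convolutional VAE over binned multimodal tracks.

The encoder applies a stack of valid Conv1d layers (each followed by
BatchNorm, ReLU and Dropout) to the (N, M, G) log1p counts — modalities
are channels, bins are positions — flattens channel-major, concatenates
the batch one-hot, passes one hidden FC block, and maps linearly to
(mu, log sigma^2). The decoder is a single linear map from (z, b) to the
flattened final feature-map size, unflattened and run through mirrored
transposed convolutions; the last transposed convolution emits exactly M
channels with no normalization or activation, the output is cropped or
zero-logit-padded to G bins, and a per-channel softmax scaled by the
library size yields the Poisson (or NB) rates. Pooling is absent: a
large stride plays its role.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import nn
from .models_base import (
    LayerSummary,
    TrainConfig,
    VaeCore,
    as_tensor,
    minibatch_train,
    model_log_likelihood,
    prepare_inputs,
)

__all__ = [
    "conv_out_length",
    "receptive_field",
    "ConvVaeSpec",
    "ConvNetVAE",
    "build_convnet_vae",
    "count_parameters",
    "fit",
    "embed",
]

DEFAULT_CHANNELS = {1: [32], 2: [32, 64], 3: [32, 64, 128]}


def conv_out_length(length: int, kernel: int, stride: int) -> int:
    """Valid-convolution output length: floor((L - K) / S) + 1."""
    if length < kernel:
        raise ValueError(f"input length {length} < kernel {kernel}")
    return (length - kernel) // stride + 1


def receptive_field(layers) -> int:
    """Input bins seen by one output unit: 1 + sum_j (K_j - 1) prod_{j'<j} S_j'."""
    if not layers:
        raise ValueError("need at least one (kernel, stride) pair")
    rf, jump = 1, 1
    for kernel, stride in layers:
        rf += (kernel - 1) * jump
        jump *= stride
    return rf


@dataclass
class ConvVaeSpec:
    """Declarative ConvNet-VAE architecture description."""

    n_modalities: int
    n_bins: int
    n_batches: int
    latent_dim: int = 30
    n_conv_layers: int = 1
    kernel: int = 31
    stride: int | None = None
    channels: list[int] | None = None
    hidden_fc: int = 128
    dropout: float = 0.2
    likelihood: str = "poisson"

    def __post_init__(self):
        if self.stride is None:
            self.stride = self.kernel
        if self.channels is None:
            self.channels = list(DEFAULT_CHANNELS[self.n_conv_layers])
        if len(self.channels) != self.n_conv_layers:
            raise ValueError("channels length must equal n_conv_layers")
        if not (1 <= self.stride <= self.kernel):
            raise ValueError("require 1 <= stride <= kernel")
        stack = [(self.kernel, self.stride)] * self.n_conv_layers
        if self.n_bins < receptive_field(stack):
            raise ValueError(f"n_bins {self.n_bins} smaller than the receptive "
                             f"field {receptive_field(stack)}")

    @property
    def conv_lengths(self) -> list[int]:
        lengths = [self.n_bins]
        for _ in range(self.n_conv_layers):
            lengths.append(conv_out_length(lengths[-1], self.kernel, self.stride))
        return lengths


class _ConvCore(VaeCore):
    def __init__(self, spec: ConvVaeSpec, rng: np.random.Generator):
        self.spec = spec
        self.latent_dim = spec.latent_dim
        self.likelihood = spec.likelihood
        lengths = spec.conv_lengths
        chans = [spec.n_modalities] + spec.channels

        enc_layers = []
        for j in range(spec.n_conv_layers):
            enc_layers += [nn.Conv1d(chans[j], chans[j + 1], spec.kernel, spec.stride, rng),
                           nn.BatchNorm1d(chans[j + 1]), nn.ReLU(),
                           nn.Dropout(spec.dropout, rng)]
        enc_layers.append(nn.Flatten())
        self.enc_conv = nn.Sequential(*enc_layers)
        self.flat_size = spec.channels[-1] * lengths[-1]
        self.enc_fc = nn.Sequential(
            nn.Linear(self.flat_size + spec.n_batches, spec.hidden_fc, rng),
            nn.BatchNorm1d(spec.hidden_fc), nn.ReLU(), nn.Dropout(spec.dropout, rng),
            nn.Linear(spec.hidden_fc, 2 * spec.latent_dim, rng))

        self.dec_fc = nn.Linear(spec.latent_dim + spec.n_batches, self.flat_size, rng)
        dec_layers = [nn.Unflatten(spec.channels[-1], lengths[-1])]
        rev = list(reversed(spec.channels))  # e.g. [128, 64, 32]
        for j in range(spec.n_conv_layers - 1):
            dec_layers += [nn.ConvTranspose1d(rev[j], rev[j + 1], spec.kernel,
                                              spec.stride, rng),
                           nn.BatchNorm1d(rev[j + 1]), nn.ReLU(),
                           nn.Dropout(spec.dropout, rng)]
        dec_layers.append(nn.ConvTranspose1d(rev[-1], spec.n_modalities,
                                             spec.kernel, spec.stride, rng))
        self.dec_stack = nn.Sequential(*dec_layers)
        if spec.likelihood == "nb":
            self.log_theta = nn.Layer()
            self.log_theta.params["log_theta"] = np.zeros((spec.n_modalities, spec.n_bins))
            self.log_theta.zero_grad()

    # -- forward/backward hooks ------------------------------------------
    def _encode(self, xlog, onehot, training):
        flat = self.enc_conv.forward(xlog, training=training)
        return self.enc_fc.forward(np.concatenate([flat, onehot], axis=1),
                                   training=training)

    def _encode_backward(self, dout):
        dcat = self.enc_fc.backward(dout)
        self.enc_conv.backward(dcat[:, :self.flat_size])

    def _decode(self, z, onehot, training):
        flat = self.dec_fc.forward(np.concatenate([z, onehot], axis=1),
                                   training=training)
        rho = self.dec_stack.forward(flat, training=training)
        g = self.spec.n_bins
        self._dec_out_len = rho.shape[2]
        if rho.shape[2] > g:
            rho = rho[:, :, :g]
        elif rho.shape[2] < g:
            pad = np.zeros((rho.shape[0], rho.shape[1], g - rho.shape[2]))
            rho = np.concatenate([rho, pad], axis=2)
        return rho

    def _decode_backward(self, drho):
        l_out = self._dec_out_len
        g = self.spec.n_bins
        if l_out > g:
            drho = np.concatenate(
                [drho, np.zeros((drho.shape[0], drho.shape[1], l_out - g))], axis=2)
        elif l_out < g:
            drho = drho[:, :, :l_out]
        dflat = self.dec_stack.backward(drho)
        dcat = self.dec_fc.backward(dflat)
        return dcat[:, :self.spec.latent_dim]

    def param_handles(self):
        handles = []
        for seq in (self.enc_conv, self.enc_fc, self.dec_stack):
            handles += [(layer, name) for layer, name, _, _ in seq.param_items()]
        handles += [(self.dec_fc, name) for name in self.dec_fc.params]
        if self.likelihood == "nb":
            handles.append((self.log_theta, "log_theta"))
        return handles

    def layer_summaries(self) -> list[LayerSummary]:
        spec, lengths = self.spec, self.spec.conv_lengths
        rows = []
        chans = [spec.n_modalities] + spec.channels
        for j in range(spec.n_conv_layers):
            conv = [l for l in self.enc_conv.layers if isinstance(l, nn.Conv1d)][j]
            bn = [l for l in self.enc_conv.layers if isinstance(l, nn.BatchNorm1d)][j]
            rows.append(LayerSummary(f"encoder.conv{j}", (chans[j], lengths[j]),
                                     (chans[j + 1], lengths[j + 1]), conv.n_params))
            rows.append(LayerSummary(f"encoder.bn{j}", (chans[j + 1], lengths[j + 1]),
                                     (chans[j + 1], lengths[j + 1]), bn.n_params))
        fc, bn_fc, head = (self.enc_fc.layers[0], self.enc_fc.layers[1],
                           self.enc_fc.layers[4])
        rows.append(LayerSummary("encoder.fc", (self.flat_size + spec.n_batches,),
                                 (spec.hidden_fc,), fc.n_params))
        rows.append(LayerSummary("encoder.bn_fc", (spec.hidden_fc,), (spec.hidden_fc,),
                                 bn_fc.n_params))
        rows.append(LayerSummary("encoder.fc_mu_sigma", (spec.hidden_fc,),
                                 (2 * spec.latent_dim,), head.n_params))
        rows.append(LayerSummary("decoder.fc", (spec.latent_dim + spec.n_batches,),
                                 (self.flat_size,), self.dec_fc.n_params))
        tconvs = [l for l in self.dec_stack.layers if isinstance(l, nn.ConvTranspose1d)]
        bns = [l for l in self.dec_stack.layers if isinstance(l, nn.BatchNorm1d)]
        rev_len = list(reversed(lengths))
        for j, tc in enumerate(tconvs):
            rows.append(LayerSummary(f"decoder.tconv{j}",
                                     (tc.in_channels, rev_len[j]),
                                     (tc.out_channels, tc.out_length(rev_len[j])),
                                     tc.n_params))
            if j < len(bns):
                rows.append(LayerSummary(f"decoder.bn{j}",
                                         (tc.out_channels,), (tc.out_channels,),
                                         bns[j].n_params))
        if self.likelihood == "nb":
            rows.append(LayerSummary("nb.log_theta", (spec.n_modalities, spec.n_bins),
                                     (spec.n_modalities, spec.n_bins),
                                     self.log_theta.n_params))
        return rows


def build_convnet_vae(spec: ConvVaeSpec, seed: int = 0) -> _ConvCore:
    """Instantiate the network for a spec (random init from the seed)."""
    return _ConvCore(spec, np.random.default_rng(seed))


def count_parameters(core) -> tuple[int, list[LayerSummary]]:
    """Total trainable parameters and the per-layer breakdown.

    Counts weights, biases and batch-norm affine pairs; running batch-norm
    statistics are not trainable and are excluded.
    """
    rows = core.layer_summaries()
    return sum(r.n_params for r in rows), rows


class ConvNetVAE(TransformerMixin, BaseEstimator):
    """Scikit-learn style estimator wrapping the convolutional VAE.

    Parameters mirror :class:`ConvVaeSpec` plus the training settings.
    ``fit`` expects a :class:`~convvae.data.MultimodalTensor`;
    ``transform`` returns the posterior means (N x latent_dim) with
    dropout and batch norm in inference mode.

    Attributes (after fit)
    ----------------------
    core_ : the trained network
    loss_history_ : per-epoch mean negative ELBO
    n_parameters_ : trainable parameter count
    batch_levels_ : batch categories seen during fit
    """

    def __init__(self, n_conv_layers=1, kernel=31, stride=None, channels=None,
                 hidden_fc=128, latent_dim=30, dropout=0.2, likelihood="poisson",
                 conditional=True, batch_size=128, learning_rate=1e-3,
                 epochs=50, seed=0):
        self.n_conv_layers = n_conv_layers
        self.kernel = kernel
        self.stride = stride
        self.channels = channels
        self.hidden_fc = hidden_fc
        self.latent_dim = latent_dim
        self.dropout = dropout
        self.likelihood = likelihood
        self.conditional = conditional
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.seed = seed

    def _spec(self, tensor, n_batches):
        return ConvVaeSpec(n_modalities=tensor.n_modalities, n_bins=tensor.n_bins,
                           n_batches=n_batches, latent_dim=self.latent_dim,
                           n_conv_layers=self.n_conv_layers, kernel=self.kernel,
                           stride=self.stride,
                           channels=None if self.channels is None else list(self.channels),
                           hidden_fc=self.hidden_fc, dropout=self.dropout,
                           likelihood=self.likelihood)

    def fit(self, X, y=None):
        tensor = as_tensor(X)
        x, lib, onehot, levels = prepare_inputs(tensor, self.conditional)
        spec = self._spec(tensor, onehot.shape[1])
        core = build_convnet_vae(spec, seed=self.seed)
        cfg = TrainConfig(batch_size=self.batch_size, learning_rate=self.learning_rate,
                          epochs=self.epochs, seed=self.seed)
        optimizer = nn.Adam(core.param_handles(), lr=cfg.learning_rate)
        self.loss_history_ = minibatch_train(core, x, lib, onehot, cfg, optimizer)
        self.core_ = core
        self.spec_ = spec
        self.batch_levels_ = levels
        self.n_parameters_ = count_parameters(core)[0]
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
        """Single-sample ELBO estimate (mean per cell) on held-out data."""
        check_is_fitted(self, "core_")
        tensor = as_tensor(X)
        x, lib, onehot, _ = prepare_inputs(tensor, self.conditional)
        onehot = self._design(tensor)
        return self.core_.eval_elbo(x, lib, onehot, seed=seed)

    def log_likelihood(self, X, n_samples: int = 100, seed: int = 0,
                       return_per_cell: bool = False):
        """Importance-sampled marginal log p(X | b), mean over cells."""
        check_is_fitted(self, "core_")
        tensor = as_tensor(X)
        x, lib, _, _ = prepare_inputs(tensor, self.conditional)
        onehot = self._design(tensor)
        return model_log_likelihood(self.core_, x, lib, onehot,
                                    n_samples=n_samples, seed=seed,
                                    return_per_cell=return_per_cell)

    def layer_summary(self) -> list[LayerSummary]:
        check_is_fitted(self, "core_")
        return self.core_.layer_summaries()


def fit(model: ConvNetVAE, tensor, cfg: TrainConfig | None = None) -> ConvNetVAE:
    """Functional wrapper: train ``model`` on ``tensor`` (optionally with cfg)."""
    if cfg is not None:
        model.set_params(batch_size=cfg.batch_size, learning_rate=cfg.learning_rate,
                         epochs=cfg.epochs, seed=cfg.seed)
    return model.fit(tensor)


def embed(model: ConvNetVAE, tensor) -> np.ndarray:
    """Posterior means of the fitted model: the cell embedding."""
    return model.transform(tensor)
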