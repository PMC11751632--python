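# convvae

Convolutional variational autoencoders for integrating single-cell
multimodal epigenomic data.

Assays such as nano-CUT&Tag and scNTT-seq measure several epigenomic
layers — histone modifications like H3K27ac and H3K27me3, and chromatin
accessibility — in the same cell. Each modality is a 1D track over the
genome, and all modalities are observed at the same genomic positions.
After tiling the genome into fixed-width bins (10 kb by default), the
data for a cell is a modality × bin matrix of fragment counts, and a
dataset is a cell × modality × bin tensor. This package treats that
tensor as a **multichannel 1D signal** (modalities = channels, bins =
positions) and learns a joint low-dimensional, batch-corrected cell
embedding with a 1D-convolutional VAE. It is aimed at computational
biologists analyzing single-cell multimodal chromatin profiling data,
and at methodologists comparing convolutional and fully connected
integration architectures.

## Model

For cell *i*, modality *m* and bin *g*, with latent factor
*z<sub>i</sub>* ~ N(0, I<sub>D</sub>), one-hot batch label
*b<sub>i</sub>*, and modality library size
*l<sub>mi</sub>* = Σ<sub>g</sub> x<sub>mgi</sub>:

```
rho_i    = Decoder(z_i, b_i)                    # logits, one channel per modality
w_mgi    = softmax_g(rho_mgi)                   # softmax over bins within a modality
lambda_mgi = w_mgi * l_mi
x_mgi   ~ Poisson(lambda_mgi)                   # or NB with per-feature dispersion
```

The encoder is a stack of 1–3 valid Conv1d layers (kernel K, stride S;
BatchNorm + ReLU + Dropout after each), flattened and concatenated with
the batch one-hot, followed by one hidden FC layer and a linear map to
(μ, log σ²). The decoder is a single linear map from (z, b) to the
flattened feature-map size, mirrored transposed convolutions, and a
per-channel softmax. Modalities are conditionally independent given
(z, b), so the reconstruction term sums over channels and bins.

The baseline is a **product-of-experts FC-VAE**: one fully connected
encoder/decoder pair per modality; the per-modality Gaussian posteriors
(μ<sub>m</sub>, V<sub>m</sub>) are fused with a standard-normal prior
expert by multiplying densities — precisions add,
Σ<sub>PoE</sub> = (Σ<sub>m</sub> T<sub>m</sub>)⁻¹, means are
precision-weighted. Because convolution shares weights along the genome,
the conv model needs a small fraction of the FC baseline's parameters
(20–33% bimodal, down to 13% trimodal at K = S = 51), and the gap grows
with the number of modalities.

Both models are exposed as scikit-learn style estimators (`fit`,
`transform`, `get_params`); all neural-network layers, backpropagation
and Adam live in `convvae.nn` on plain numpy. Marginal log-likelihood
log p(X | b) is estimated by importance sampling with the variational
posterior as proposal (log-sum-exp over 100 draws by default).

## Worked example

```python
import numpy as np
from convvae import ConvNetVAE, SimConfig, simulate_dataset
from convvae.evaluation import louvain_sweep, ari

cfg = SimConfig(seed=1, batch_effect_sd=0.0)   # 600 cells x 2 marks x 512 bins
tensor, truth = simulate_dataset(cfg)

model = ConvNetVAE(kernel=51, stride=51, latent_dim=30, epochs=60, seed=1)
model.fit(tensor)
print(f"trainable parameters: {model.n_parameters_:,}")
print(f"loss: {model.loss_history_[0]:.1f} (epoch 1) -> {model.loss_history_[-1]:.1f} (epoch 60)")

emb = model.transform(tensor)                  # posterior means, 600 x 30
best = max(louvain_sweep(emb, [0.2, 0.4, 0.6, 0.8, 1.0], seed=1),
           key=lambda r: ari(truth.cluster_of_cell, r.assignments))
print(f"Louvain: {best.n_clusters} clusters at resolution {best.resolution}, "
      f"ARI vs ground truth = {ari(truth.cluster_of_cell, best.assignments):.3f}")
```

prints

```
trainable parameters: 66,526
loss: 141.2 (epoch 1) -> 122.6 (epoch 60)
Louvain: 4 clusters at resolution 0.2, ARI vs ground truth = 1.000
```

The synthetic dataset has four cell types with peaky, spatially
autocorrelated rate profiles and ~15 fragments per cell and modality;
the 66 k-parameter conv model recovers the generating clusters exactly
(adjusted Rand index 1.0). Training minimizes the negative evidence
lower bound, so the loss column is the per-cell −ELBO.

A command-line interface covers the same pipeline from fragment files:

```
convvae simulate --out data/            # or: convvae bin --fragments ... --chrom-sizes ...
convvae train --counts data/ --model conv --kernel 51 --stride 51 --out model.pkl
convvae embed --model model.pkl --counts data/ --out embeddings.csv
convvae evaluate --embeddings embeddings.csv --labels data/cell_types.tsv \
    --batches data/batches.tsv --out report.json
```

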