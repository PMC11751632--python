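# Methods

## Generative model

Counts are modeled per cell *i*, modality *m*, bin *g* as
x<sub>mgi</sub> ~ Poisson(λ<sub>mgi</sub>) with
λ<sub>mgi</sub> = w<sub>mgi</sub> · l<sub>mi</sub>, where
w<sub>m·i</sub> = softmax over the G bins of the decoder logits for
channel *m*, and l<sub>mi</sub> is the observed per-cell, per-modality
library size (never learned). Because the softmax normalizes within a
channel, Σ<sub>g</sub> λ<sub>mgi</sub> = l<sub>mi</sub> exactly: the
model allocates a cell's sequencing depth across the genome rather than
predicting it. The latent prior is N(0, I<sub>D</sub>); the variational
posterior is a diagonal Gaussian. An optional negative binomial
likelihood adds one dispersion parameter θ<sub>mg</sub> per feature
(modality × bin), shared across cells and learned jointly as free
log-θ initialized at 0; with θ → ∞ it recovers the Poisson. On data
without strong overdispersion the two likelihoods behave nearly
identically, so Poisson is the default.

Training maximizes the single-sample Monte-Carlo ELBO: reconstruction
log-likelihood summed over modalities and bins (channels are
conditionally independent given z and b), minus
KL(q(z|X, b) ‖ N(0, I)), averaged over cells. Summing (rather than
averaging) over bins keeps the objective an actual evidence bound.

## Architectures

**ConvNet-VAE.** Encoder: 1–3 valid (unpadded) Conv1d layers with
kernel K and stride S — stride, not pooling, performs downsampling —
each followed by BatchNorm1d, ReLU and Dropout; channel counts 32, 64,
128. The feature map is flattened channel-major, concatenated with the
B-dim batch one-hot, passed through one hidden FC block
(128 units + BN + ReLU + Dropout) and a linear layer to (μ, log σ²).
Decoder: one *linear* FC layer from (z, b) to the flattened feature-map
size (no hidden layer, no BN/activation), unflattened, then mirrored
transposed convolutions with the same (K, S); intermediate layers carry
BN + ReLU + Dropout, the final one emits exactly M channels with no
normalization or activation. Valid convolution makes the reconstructed
length (L−1)·S + K, which can undershoot G when G is not divisible by
S; the logits are zero-padded (or cropped) to exactly G before the
softmax. Batch covariates never enter as an input channel: convolutions
suit sequential data, so the one-hot joins after the flatten (encoder)
and beside z (decoder).

Output length follows floor((L − K)/S) + 1 and the receptive field
RF = 1 + Σ<sub>j</sub> (K<sub>j</sub> − 1) Π<sub>j′<j</sub> S<sub>j′</sub>;
both are verified in the tests against perturbation probing of randomly
initialized stacks. Chromosome tracks are concatenated in the order of
the chromosome-sizes file; kernels may straddle a chromosome boundary.
No cross-chromosome masking is applied — with bins ≫ boundaries the
effect is negligible, and small kernels localize it.

**PoE FC-VAE.** One expert per modality: encoder
[FC(128) + BN + ReLU + Dropout] × L (L = 1–3) then a linear layer to
(μ<sub>m</sub>, log V<sub>m</sub>); decoder mirrors with a final linear
layer to G logits. Experts are fused as a product of Gaussians with a
standard-normal prior pseudo-expert included in the sums (precisions
add; means precision-weighted); a flag disables the prior expert for
ablation. The fusion enters the prior once — the alternative reading,
tilting every expert by the prior, would multiply the prior in M times
and over-concentrate the posterior. Library sizes and likelihoods are
identical to the conv model so the two are comparable
likelihood-for-likelihood.

**Parameter counting** includes weights, biases and batch-norm affine
pairs (γ, β); running statistics are not trainable and are excluded.
Under these conventions the single-conv-layer bimodal models use 20%
(K = S = 51) and 33% (K = S = 31) of the one-hidden-layer FC baseline's
12.88 M parameters, and the trimodal models save 87% (K = S = 51) and
39% (K = S = 11) — the convolution's weight sharing is what makes the
count independent of G except through the flatten/FC interface.

## Training

Adam (learning rate 10⁻³), mini-batch 128, dropout 0.2, latent
dimension 30 by default. The encoder consumes log1p-transformed counts
for numerical stability; likelihoods always evaluate raw counts.
Log-variances are clipped to ±15. All sums accumulate in float64. Every
stochastic element (initialization, mini-batch order, dropout masks,
reparameterization noise) draws from generators derived from the
estimator's `seed`, so runs are bit-reproducible on one machine. A
non-finite loss aborts with the epoch and batch offset.

The whole network stack (Conv1d / ConvTranspose1d via im2col and its
adjoint, BatchNorm1d, Dropout, Adam) is implemented in numpy with
hand-derived backpropagation; every layer's analytic gradient is
checked against central finite differences in the test suite, and the
convolution forward pass against `scipy.signal.correlate`. The gradient
of the reconstruction term with respect to the decoder logits uses the
closed form l·w·(a − Σ w a) (for Poisson simply w·l − x), which avoids
materializing the softmax Jacobian.

## Marginal likelihood

log p(X | b) is estimated per cell by importance sampling with the
trained posterior as proposal: log (1/N<sub>s</sub>) Σ<sub>s</sub>
p(X | z<sub>s</sub>, b) p(z<sub>s</sub>) / q(z<sub>s</sub> | X, b),
computed with log-sum-exp; N<sub>s</sub> = 100 by default. On a
linear-Gaussian toy model with an analytic marginal the estimator is
exact when the proposal equals the true posterior and converges within
Monte-Carlo error otherwise; the single-sample ELBO lower-bounds it.

## Integration metrics

Batch-effect removal: ASW(batch) (per cell type, mean 1 − |silhouette|
over batch labels), graph connectivity (largest same-type connected
component fraction in the k = 20 kNN graph), graph iLISI and kBET.
Biological conservation: ASW(cell type) ((silhouette + 1)/2), NMI
(arithmetic normalization, reported at the Louvain resolution that
maximizes it over the sweep, with the full sweep exposed), graph cLISI.
Overall score = 0.4 · mean(batch metrics) + 0.6 · mean(bio metrics).

LISI is computed in embedding space with a Gaussian kernel calibrated
per cell to a fixed perplexity (30) over the 3·perplexity nearest
neighbors, aggregated by the median and rescaled to [0, 1] —
(median − 1)/(B − 1) for batches, (C − median)/(C − 1) for types. kBET
is simplified to a Pearson χ² test of each cell's k₀ = 50 neighborhood
batch composition against its cell type's global composition
(acceptance = fraction of p > 0.05); the original adaptive-k,
Monte-Carlo procedure is not reproduced. Both are deliberate,
documented deviations from the scIB implementations, which these
scores numerically approximate but do not replicate. Louvain runs on
the union-symmetrized exact kNN graph via igraph with five seeded
restarts per resolution, keeping the best-modularity assignment (ties:
lowest restart index).

## Synthetic data generator

Each cluster's rate profile per modality is a flat baseline plus
Gaussian bumps: peak centers uniform over bins, widths
`peak_width_bins` (3 bins), heights uniform in [2, 6], normalized over
bins. A `shared_peak_fraction` (0.5) of centers is common to all
modalities; for declared anticorrelated modality pairs the shared
centers are split alternately between the two channels, so loci active
in one are silent in the other, mimicking activating vs repressive
marks. Batch effects multiply rates bin-wise by LogNormal(0, sd)
factors and are renormalized, so library sizes remain exactly the drawn
l<sub>mi</sub> ~ LogNormal. Counts are Poisson. Defaults: 600 cells, 2
modalities, 512 bins, 4 balanced clusters, 2 balanced batches, 20 peaks
per cluster, batch sd 0.3, and a library of ~15 fragments per cell and
modality — single-cell chromatin data is extremely sparse per bin, and
15 fragments over 512 bins matches the per-window share of a realistic
genome-wide library. Gaussian bumps were chosen over autoregressive
smoothing because the spatial correlation length is then a single
interpretable knob.

The generator can emit fragment files whose re-binning reproduces the
tensor exactly (fragments never cross bin boundaries), providing a
round-trip oracle for the binning stage. It does **not** emulate
realistic fragment-length distributions, Tn5 insertion bias, doublets,
zero-inflation, or peak co-occurrence structure beyond pairwise
sharing; passing the synthetic benchmarks therefore demonstrates
correctness of the machinery and the claimed qualitative behaviors, not
performance on real tissue.

## Benchmark problem sizes and observed behavior

The standard benchmark trains on the generator defaults
(600 × 2 × 512). Cluster recovery uses batch sd 0 to isolate cluster
structure: the K = S = 51 conv model at 60 epochs reaches Louvain
ARI ≥ 0.9 (typically 1.0), and training the identical model on a
bin-shuffled copy of the same data is strictly worse — in the sparse
regime a 51-bin window compressed to 32 channels preserves smooth
aligned profiles but not scattered ones, and the effect grows with
kernel size. The batch-conditioning comparison uses batch sd 1.0:
conditional training improves ASW(batch) by well over 0.05 and kBET
strictly, relative to the same model trained without the batch
covariate. At ~30+ fragments per cell every configuration saturates
(ARI 1.0 shuffled or not), which is why the benchmark sits in the
sparse regime. These sizes keep the full suite under a minute of CPU.

## Preprocessing conventions

Coordinates are BED (0-based, half-open) throughout. A fragment
overlapping k bins contributes its count to each of them (feature-style
counting; insertion-site counting is a plausible alternative the
upstream tooling does not specify). Blacklist filtering removes bins
with ≥ 1 bp overlap. Read counts convert to fragment counts as
ceil(r/2). Joint top-bin selection grows per-modality descending-count
rank lists (ties to the lower genome index) to the smallest depth k
whose union reaches `n_top`, then trims to exactly `n_top` by best
per-modality rank, ties again by genome index — deterministic and
symmetric in modality order. Degenerate all-zero cells are tolerated
(λ = 0, x = 0 contributes log-probability 0) and logged.

## Known limitations

All modalities must share one bin set; missing modalities are not
supported. The dense cell × modality × bin tensor must fit in memory at
mini-batch scale. The numpy training loop is single-threaded BLAS-bound
and suited to desk-scale data (up to ~10⁴ cells × ~10³ bins); it is not
a GPU implementation. kBET and LISI approximate, and do not replicate,
the reference implementations.
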