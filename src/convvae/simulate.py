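"""Synthetic multichannel single-cell epigenomic counts with ground truth.

Cells belong to one of C clusters; each cluster has a per-modality rate
profile over G bins built from a flat baseline plus Gaussian bumps
("peaks") whose width sets the spatial autocorrelation length of the
signal. A fraction of peak centers is shared across modalities
(cross-modality coupling at common loci); for anticorrelated modality
pairs, shared peaks present in one channel are suppressed in the other
(activating vs repressive marks, e.g. H3K27ac vs H3K27me3). Batch
effects multiply the rates bin-wise (log-normal) before renormalization,
so per-cell library sizes are exactly the drawn l_mi. Counts are Poisson:

    x_img ~ Poisson(l_mi * normalize_g(profile[c, m] * batch_factor[b, m]))

The generator can also emit per-modality fragment files that reproduce
the tensor exactly when re-binned (no fragment crosses a bin boundary),
giving the binning stage a round-trip oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .binning import make_genome_bins
from .data import BinSet, MultimodalTensor

__all__ = ["SimConfig", "SimTruth", "simulate_profiles", "simulate_cells",
           "simulate_dataset", "simulate_fragments", "write_fragment_files"]


@dataclass
class SimConfig:
    """Study conditions for the synthetic benchmark.

    Defaults emulate a desk-scale version of a multimodal CUT&Tag-style
    experiment: a few hundred cells, two histone-mark channels, ~500
    bins, four cell types over two batches. Library sizes default to
    ~15 fragments per cell and modality — single-cell chromatin
    profiling is extremely sparse per bin, and this is the per-window
    share of a realistic genome-wide library scaled down to 512 bins.
    """

    n_cells: int = 600
    n_modalities: int = 2
    n_bins: int = 512
    n_clusters: int = 4
    n_batches: int = 2
    peaks_per_cluster: int = 20
    peak_width_bins: float = 3.0
    shared_peak_fraction: float = 0.5
    anticorrelated_modality_pairs: list = field(default_factory=list)
    batch_effect_sd: float = 0.3
    library_log_mean: float = float(np.log(15.0))
    library_log_sd: float = 0.3
    baseline_level: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.shared_peak_fraction <= 1.0:
            raise ValueError("shared_peak_fraction must lie in [0, 1]")
        if min(self.peak_width_bins, self.baseline_level) <= 0:
            raise ValueError("scales must be positive")
        if self.batch_effect_sd < 0:
            raise ValueError("batch_effect_sd must be >= 0")


@dataclass
class SimTruth:
    """Ground truth of one simulation."""

    profiles: np.ndarray                  # (C, M, G), each (c, m) sums to 1
    batch_factors: np.ndarray             # (B, M, G), positive
    cluster_of_cell: np.ndarray | None = None
    batch_of_cell: np.ndarray | None = None


def simulate_profiles(cfg: SimConfig, rng: np.random.Generator | None = None) -> SimTruth:
    """Cluster x modality x bin rate profiles (normalized over bins)."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    c, m, g = cfg.n_clusters, cfg.n_modalities, cfg.n_bins
    grid = np.arange(g)
    profiles = np.full((c, m, g), cfg.baseline_level, dtype=np.float64)
    anti = {tuple(sorted(p)) for p in cfg.anticorrelated_modality_pairs}
    for ci in range(c):
        n_shared = int(round(cfg.shared_peak_fraction * cfg.peaks_per_cluster))
        shared_centers = rng.uniform(0, g, size=n_shared)
        for mi in range(m):
            own_centers = rng.uniform(0, g, size=cfg.peaks_per_cluster - n_shared)
            heights_shared = rng.uniform(2.0, 6.0, size=n_shared)
            heights_own = rng.uniform(2.0, 6.0, size=len(own_centers))
            suppress = np.zeros(n_shared, dtype=bool)
            for (a, b) in anti:
                # split shared peaks between the two channels so that loci
                # active in one are silent in the other (activating vs
                # repressive mark)
                if mi == a:
                    suppress |= np.arange(n_shared) % 2 == 1
                elif mi == b:
                    suppress |= np.arange(n_shared) % 2 == 0
            for center, h, sup in zip(shared_centers, heights_shared, suppress):
                if sup:
                    continue
                profiles[ci, mi] += h * np.exp(-0.5 * ((grid - center)
                                                       / cfg.peak_width_bins) ** 2)
            for center, h in zip(own_centers, heights_own):
                profiles[ci, mi] += h * np.exp(-0.5 * ((grid - center)
                                                       / cfg.peak_width_bins) ** 2)
    profiles /= profiles.sum(axis=2, keepdims=True)
    batch_factors = np.exp(rng.normal(0.0, cfg.batch_effect_sd,
                                      size=(cfg.n_batches, m, g)))
    if cfg.batch_effect_sd == 0:
        batch_factors = np.ones_like(batch_factors)
    return SimTruth(profiles=profiles, batch_factors=batch_factors)


def simulate_cells(truth: SimTruth, cfg: SimConfig,
                   rng: np.random.Generator | None = None,
                   bins: BinSet | None = None) -> tuple[MultimodalTensor, SimTruth]:
    """Draw the count tensor: balanced cluster/batch assignment, Poisson counts."""
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    n, m, g = cfg.n_cells, cfg.n_modalities, cfg.n_bins
    clusters = np.arange(n) % cfg.n_clusters
    batches = (np.arange(n) // cfg.n_clusters) % cfg.n_batches
    perm = rng.permutation(n)
    clusters, batches = clusters[perm], batches[perm]
    lib = rng.lognormal(cfg.library_log_mean, cfg.library_log_sd, size=(n, m))
    rates = truth.profiles[clusters] * truth.batch_factors[batches]   # (N, M, G)
    rates /= rates.sum(axis=2, keepdims=True)
    counts = rng.poisson(lib[:, :, None] * rates)
    if bins is None:
        bins = make_genome_bins([("chrSim", g * 1000)], 1000)
    tensor = MultimodalTensor(
        counts=[sp.csr_matrix(counts[:, mi, :]) for mi in range(m)],
        cell_barcodes=np.array([f"cell{i:05d}" for i in range(n)], dtype=object),
        modality_names=[f"mod{mi}" for mi in range(m)],
        bins=bins,
        batch_labels=np.array([f"batch{b}" for b in batches], dtype=object),
        cell_type_labels=np.array([f"cluster{c}" for c in clusters], dtype=object))
    full = SimTruth(profiles=truth.profiles, batch_factors=truth.batch_factors,
                    cluster_of_cell=clusters, batch_of_cell=batches)
    return tensor, full


def simulate_dataset(cfg: SimConfig) -> tuple[MultimodalTensor, SimTruth]:
    """Profiles + cells in one seeded call."""
    rng = np.random.default_rng(cfg.seed)
    truth = simulate_profiles(cfg, rng)
    return simulate_cells(truth, cfg, rng)


def simulate_fragments(tensor: MultimodalTensor, seed: int = 0):
    """Per-modality fragment record lists that re-bin to the exact tensor.

    For every nonzero count, that many fragments are emitted with start
    uniform inside the bin and end = start + min(200 bp, remaining bin
    span), so no fragment crosses a bin boundary.
    """
    from .binning import FragmentRecord

    bins = tensor.bins
    if int(np.min(bins.ends - bins.starts)) < 2:
        raise ValueError("bins must be at least 2 bp wide")
    rng = np.random.default_rng(seed)
    streams = []
    for mat in tensor.counts:
        coo = sp.coo_matrix(mat)
        frags = []
        for i, g, c in zip(coo.row, coo.col, coo.data):
            bstart, bend = int(bins.starts[g]), int(bins.ends[g])
            starts = rng.integers(bstart, bend - 1, size=int(c))
            for s in starts:
                e = min(int(s) + 200, bend)
                frags.append(FragmentRecord(str(bins.chroms[g]), int(s), e,
                                            str(tensor.cell_barcodes[i]), 1))
        streams.append(frags)
    return streams


def write_fragment_files(tensor: MultimodalTensor, outdir: str | Path,
                         seed: int = 0) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, frags in zip(tensor.modality_names, simulate_fragments(tensor, seed)):
        path = outdir / f"fragments_{name}.tsv"
        with open(path, "w") as fh:
            for f in sorted(frags, key=lambda f: (f.chrom, f.start)):
                fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.barcode}\t{f.count}\n")
        paths.append(path)
    return paths
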