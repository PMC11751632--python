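"""Core data containers for binned multimodal epigenomic counts.

The central object is :class:`MultimodalTensor`: a cell x modality x bin
array of non-negative integer fragment counts, where every modality (an
epigenomic track such as H3K27ac, H3K27me3 or ATAC) is one channel of a
1D signal over genomic bins. Counts are stored sparsely per modality
(CSR) and densified only when a mini-batch is assembled.

Coordinates follow the BED convention: 0-based, half-open intervals.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "BinSet",
    "MultimodalTensor",
    "LibrarySizes",
    "BatchDesign",
    "log1p_channels",
    "library_sizes",
    "shuffle_bins",
    "save_tensor",
    "load_tensor",
]


@dataclass(frozen=True)
class BinSet:
    """Ordered genomic bins: fixed width, per-chromosome, genome order.

    Within a chromosome, bins are contiguous, non-overlapping and sorted
    by start; the global order is chromosome-major. The last bin of each
    chromosome may be truncated (``end - start <= width``).
    """

    chroms: np.ndarray  # str per bin
    starts: np.ndarray  # int bp
    ends: np.ndarray    # int bp
    width: int

    def __post_init__(self):
        object.__setattr__(self, "chroms", np.asarray(self.chroms, dtype=object))
        object.__setattr__(self, "starts", np.asarray(self.starts, dtype=np.int64))
        object.__setattr__(self, "ends", np.asarray(self.ends, dtype=np.int64))
        if not (len(self.chroms) == len(self.starts) == len(self.ends)):
            raise ValueError("chroms/starts/ends length mismatch")
        if np.any(self.ends - self.starts > self.width) or np.any(self.ends <= self.starts):
            raise ValueError("bin intervals must satisfy 0 < end - start <= width")

    def __len__(self) -> int:
        return len(self.starts)

    def subset(self, indices: np.ndarray) -> "BinSet":
        idx = np.asarray(indices)
        return BinSet(self.chroms[idx], self.starts[idx], self.ends[idx], self.width)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chroms, "start": self.starts, "end": self.ends})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, width: int) -> "BinSet":
        return cls(df["chrom"].to_numpy(dtype=object), df["start"].to_numpy(),
                   df["end"].to_numpy(), width)


def _as_sparse_list(counts, n_modalities=None):
    """Normalize input (dense N x M x G or list of N x G matrices) to CSR list."""
    if isinstance(counts, (list, tuple)):
        mats = [sp.csr_matrix(c) for c in counts]
    else:
        arr = np.asarray(counts)
        if arr.ndim != 3:
            raise ValueError("dense counts must be 3D (cells x modalities x bins)")
        mats = [sp.csr_matrix(arr[:, m, :]) for m in range(arr.shape[1])]
    for m in mats:
        if m.nnz and (m.data < 0).any():
            raise ValueError("counts must be non-negative")
        if m.nnz and np.any(m.data != np.round(m.data)):
            raise ValueError("counts must be integral")
    if n_modalities is not None and len(mats) != n_modalities:
        raise ValueError("modality count mismatch")
    return mats


@dataclass
class MultimodalTensor:
    """Cell x modality x bin non-negative integer counts with labels."""

    counts: list                      # list of N x G CSR matrices, one per modality
    cell_barcodes: np.ndarray         # str[N]
    modality_names: list[str]
    bins: BinSet
    batch_labels: np.ndarray          # str[N]
    cell_type_labels: np.ndarray | None = None

    def __post_init__(self):
        self.counts = _as_sparse_list(self.counts)
        self.cell_barcodes = np.asarray(self.cell_barcodes, dtype=object)
        self.batch_labels = np.asarray(self.batch_labels, dtype=object)
        if self.cell_type_labels is not None:
            self.cell_type_labels = np.asarray(self.cell_type_labels, dtype=object)
        n, g = self.counts[0].shape
        if len(self.modality_names) != len(self.counts):
            raise ValueError("modality_names length mismatch")
        for c in self.counts:
            if c.shape != (n, g):
                raise ValueError("all modalities must share cell and bin axes")
        if len(self.bins) != g:
            raise ValueError("BinSet length must equal the bin axis")
        if len(self.cell_barcodes) != n or len(self.batch_labels) != n:
            raise ValueError("per-cell labels must have length N")

    @property
    def n_cells(self) -> int:
        return self.counts[0].shape[0]

    @property
    def n_modalities(self) -> int:
        return len(self.counts)

    @property
    def n_bins(self) -> int:
        return self.counts[0].shape[1]

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_cells, self.n_modalities, self.n_bins)

    def to_dense(self, rows: np.ndarray | None = None) -> np.ndarray:
        """Densify (a row subset of) the tensor to (n, M, G) float64."""
        mats = self.counts if rows is None else [c[rows] for c in self.counts]
        return np.stack([np.asarray(c.todense(), dtype=np.float64) for c in mats], axis=1)

    def batch_design(self) -> "BatchDesign":
        levels = sorted(set(self.batch_labels))
        one_hot = np.zeros((self.n_cells, len(levels)))
        index = {b: j for j, b in enumerate(levels)}
        for i, b in enumerate(self.batch_labels):
            one_hot[i, index[b]] = 1.0
        return BatchDesign(one_hot=one_hot, level_names=list(levels))

    def replace(self, **kwargs) -> "MultimodalTensor":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class LibrarySizes:
    """Per-cell per-modality total fragment counts l_mi (N x M)."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.int64)
        if (v < 0).any():
            raise ValueError("library sizes must be non-negative")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class BatchDesign:
    """One-hot batch membership b_i (N x B); each row sums to 1."""

    one_hot: np.ndarray
    level_names: list

    def __post_init__(self):
        oh = np.asarray(self.one_hot, dtype=np.float64)
        if not np.allclose(oh.sum(axis=1), 1.0):
            raise ValueError("each row of the one-hot design must sum to 1")
        object.__setattr__(self, "one_hot", oh)


def log1p_channels(tensor: MultimodalTensor | np.ndarray) -> np.ndarray:
    """Element-wise ln(x + 1) of the counts; returns dense (N, M, G)."""
    dense = tensor.to_dense() if isinstance(tensor, MultimodalTensor) else np.asarray(tensor, dtype=np.float64)
    if (dense < 0).any():
        raise ValueError("counts must be non-negative")
    return np.log1p(dense)


def library_sizes(tensor: MultimodalTensor) -> LibrarySizes:
    """Sum over bins per (cell, modality)."""
    vals = np.column_stack([np.asarray(c.sum(axis=1)).ravel() for c in tensor.counts])
    return LibrarySizes(values=vals)


def shuffle_bins(tensor: MultimodalTensor, seed: int) -> MultimodalTensor:
    """Apply one seeded random permutation of bins to every cell and modality.

    The permutation is stored on the result as ``bin_permutation`` so the
    inverse can be applied. Per-cell per-modality totals are conserved.
    """
    rng = np.random.default_rng(seed)
    g = tensor.n_bins
    perm = rng.permutation(g) if g > 1 else np.arange(g)
    out = tensor.replace(counts=[c[:, perm] for c in tensor.counts],
                         bins=tensor.bins.subset(perm))
    out.bin_permutation = perm
    return out


def save_tensor(tensor: MultimodalTensor, outdir: str | Path) -> None:
    """Write MTX per modality + bins BED + barcodes/labels TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, mat in zip(tensor.modality_names, tensor.counts):
        mmwrite(str(outdir / f"counts_{name}.mtx"), sp.coo_matrix(mat))
    tensor.bins.to_frame().to_csv(outdir / "bins.bed", sep="\t", header=False, index=False)
    pd.Series(tensor.cell_barcodes).to_csv(outdir / "barcodes.tsv", header=False, index=False)
    pd.DataFrame({"barcode": tensor.cell_barcodes, "batch": tensor.batch_labels}).to_csv(
        outdir / "batches.tsv", sep="\t", header=False, index=False)
    if tensor.cell_type_labels is not None:
        pd.DataFrame({"barcode": tensor.cell_barcodes, "label": tensor.cell_type_labels}).to_csv(
            outdir / "cell_types.tsv", sep="\t", header=False, index=False)
    (outdir / "modalities.tsv").write_text("\n".join(tensor.modality_names) + "\n")
    (outdir / "bin_width.txt").write_text(str(tensor.bins.width) + "\n")


def load_tensor(indir: str | Path) -> MultimodalTensor:
    indir = Path(indir)
    modalities = (indir / "modalities.tsv").read_text().split()
    width = int((indir / "bin_width.txt").read_text().strip())
    mats = [sp.csr_matrix(mmread(str(indir / f"counts_{m}.mtx"))) for m in modalities]
    bins_df = pd.read_csv(indir / "bins.bed", sep="\t", header=None,
                          names=["chrom", "start", "end"])
    bins = BinSet.from_frame(bins_df, width=width)
    barcodes = pd.read_csv(indir / "barcodes.tsv", header=None)[0].to_numpy(dtype=object)
    batches_df = pd.read_csv(indir / "batches.tsv", sep="\t", header=None,
                             names=["barcode", "batch"])
    batches = batches_df.set_index("barcode").loc[barcodes, "batch"].to_numpy(dtype=object)
    cell_types = None
    if (indir / "cell_types.tsv").exists():
        ct = pd.read_csv(indir / "cell_types.tsv", sep="\t", header=None,
                         names=["barcode", "label"])
        cell_types = ct.set_index("barcode").loc[barcodes, "label"].to_numpy(dtype=object)
    return MultimodalTensor(counts=mats, cell_barcodes=barcodes, modality_names=modalities,
                            bins=bins, batch_labels=batches, cell_type_labels=cell_types)
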