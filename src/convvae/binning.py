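"""Fragment files to binned count tensors.

Pipeline: tile the genome into fixed-width windows (10 kb default),
drop windows overlapping a blacklist, count fragments per (cell, bin)
for each modality, jointly select the highest-count bins across
modalities, and assemble the cell x modality x bin tensor.

A fragment overlapping k bins contributes its count to each of the k
bins (Signac-style feature counting). Coordinates are BED (0-based,
half-open); a blacklist interval abutting a bin end does not remove it.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data import BinSet, MultimodalTensor

logger = logging.getLogger(__name__)

__all__ = [
    "FragmentRecord",
    "BlacklistRegions",
    "make_genome_bins",
    "filter_blacklist",
    "read_fragments",
    "count_fragments",
    "reads_to_fragments",
    "select_top_bins",
    "assemble_tensor",
]


@dataclass(frozen=True)
class FragmentRecord:
    chrom: str
    start: int
    end: int
    barcode: str
    count: int = 1

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"fragment start {self.start} >= end {self.end}")
        if self.count < 1:
            raise ValueError("fragment count must be >= 1")


@dataclass(frozen=True)
class BlacklistRegions:
    intervals: tuple  # of (chrom, start, end)

    @classmethod
    def from_bed(cls, path: str | Path) -> "BlacklistRegions":
        df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                         names=["chrom", "start", "end"])
        return cls(tuple(df.itertuples(index=False, name=None)))


def make_genome_bins(chrom_sizes, width: int) -> BinSet:
    """Tile each chromosome with ceil(length/width) bins; keep genome order.

    ``chrom_sizes`` is an ordered (name, length) sequence; the final bin
    of each chromosome is truncated at the chromosome end.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    names = [c for c, _ in chrom_sizes]
    if len(set(names)) != len(names):
        raise ValueError("duplicate chromosome names")
    chroms, starts, ends = [], [], []
    for name, length in chrom_sizes:
        if length <= 0:
            raise ValueError(f"chromosome {name} has non-positive length")
        edges = np.arange(0, length + width, width)
        edges[-1] = min(edges[-1], length)
        if edges[-1] == edges[-2]:
            edges = edges[:-1]
        chroms.extend([name] * (len(edges) - 1))
        starts.extend(edges[:-1])
        ends.extend(edges[1:])
    return BinSet(np.array(chroms, dtype=object), np.array(starts), np.array(ends), width)


def filter_blacklist(bins: BinSet, blacklist: BlacklistRegions) -> BinSet:
    """Drop every bin with >= 1 bp overlap with any blacklist interval."""
    keep = np.ones(len(bins), dtype=bool)
    for chrom, bstart, bend in blacklist.intervals:
        on_chrom = bins.chroms == chrom
        overlap = (bins.starts < bend) & (bins.ends > bstart)
        keep &= ~(on_chrom & overlap)
    return bins.subset(np.flatnonzero(keep))


def read_fragments(path: str | Path):
    """Stream FragmentRecords from a 5-column TSV, transparently gunzipping.

    Columns: chrom, start, end, barcode, count (the 10x/Signac fragments
    dialect). Malformed lines raise with their line number.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
            try:
                yield FragmentRecord(parts[0], int(parts[1]), int(parts[2]),
                                     parts[3], int(parts[4]))
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: {e}") from e


def count_fragments(fragments, bins: BinSet, barcodes) -> sp.csr_matrix:
    """Count fragments per (cell, bin): N x G sparse integer matrix.

    A fragment overlapping k bins adds its count to each. Fragments with
    unknown barcodes or chromosomes are skipped and tallied in the log.
    """
    barcode_index = {b: i for i, b in enumerate(barcodes)}
    if len(barcode_index) != len(barcodes):
        raise ValueError("barcodes must be deduplicated")
    # per-chromosome sorted bin lookup (bins are contiguous within chromosome)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in pd.unique(bins.chroms):
        idx = np.flatnonzero(bins.chroms == chrom)
        by_chrom[chrom] = (bins.starts[idx], bins.ends[idx], idx)
    rows, cols, vals = [], [], []
    skipped_barcode = skipped_chrom = 0
    for frag in fragments:
        i = barcode_index.get(frag.barcode)
        if i is None:
            skipped_barcode += 1
            continue
        lookup = by_chrom.get(frag.chrom)
        if lookup is None:
            skipped_chrom += 1
            continue
        starts, ends, idx = lookup
        lo = np.searchsorted(ends, frag.start, side="right")
        hi = np.searchsorted(starts, frag.end, side="left")
        for g in idx[lo:hi]:
            rows.append(i)
            cols.append(g)
            vals.append(frag.count)
    if skipped_barcode or skipped_chrom:
        logger.info("count_fragments skipped %d fragments with unknown barcodes, "
                    "%d with unknown chromosomes", skipped_barcode, skipped_chrom)
    mat = sp.coo_matrix((vals, (rows, cols)), shape=(len(barcodes), len(bins)),
                        dtype=np.int64)
    return mat.tocsr()


def reads_to_fragments(read_count):
    """Estimate fragment count from read (fragment-end) count: ceil(r / 2).

    Odd r maps to (r + 1) / 2, even r to r / 2; applied element-wise.
    """
    r = np.asarray(read_count)
    if (r < 0).any():
        raise ValueError("read counts must be non-negative")
    return (r + 1) // 2


def select_top_bins(per_modality_matrices, n_top: int) -> np.ndarray:
    """Jointly select the n_top highest-count bins across modalities.

    Per modality, bins are ranked by total count (descending, ties by
    lower genome index). The union of the per-modality top-k lists is
    grown with the smallest k whose union reaches n_top, then trimmed to
    exactly n_top by best (minimum) per-modality rank, ties by genome
    index. Returned indices are sorted in genome order.
    """
    totals = [np.asarray(m.sum(axis=0)).ravel() for m in per_modality_matrices]
    g = len(totals[0])
    if any(len(t) != g for t in totals):
        raise ValueError("all modalities must share the bin axis")
    if not 0 < n_top <= g:
        raise ValueError(f"n_top must be in [1, {g}]")
    # rank[m][j] = genome index of the j-th best bin of modality m
    order = [np.lexsort((np.arange(g), -t)) for t in totals]
    # rank_of[m][bin] = position of bin in modality m's ranking
    rank_of = []
    for o in order:
        r = np.empty(g, dtype=np.int64)
        r[o] = np.arange(g)
        rank_of.append(r)
    best_rank = np.min(rank_of, axis=0)
    # smallest k with |union of top-k lists| >= n_top:
    # the union at level k is exactly {bin : best_rank[bin] < k}
    counts_at_rank = np.bincount(best_rank, minlength=g)
    cum = np.cumsum(counts_at_rank)
    k = int(np.searchsorted(cum, n_top) + 1)
    union = np.flatnonzero(best_rank < k)
    trim_order = np.lexsort((union, best_rank[union]))
    selected = union[trim_order[:n_top]]
    return np.sort(selected)


def assemble_tensor(per_modality_matrices, bins: BinSet, selected_indices,
                    barcodes, batch_labels, modality_names=None,
                    cell_type_labels=None) -> MultimodalTensor:
    """Restrict per-modality matrices to selected bins and stack channels."""
    selected = np.sort(np.asarray(selected_indices))
    n = per_modality_matrices[0].shape[0]
    for m in per_modality_matrices:
        if m.shape[0] != n:
            sizes = [mm.shape[0] for mm in per_modality_matrices]
            raise ValueError(f"cell counts differ across modalities: {sizes}")
    if modality_names is None:
        modality_names = [f"mod{m}" for m in range(len(per_modality_matrices))]
    mats = [sp.csr_matrix(m)[:, selected] for m in per_modality_matrices]
    return MultimodalTensor(counts=mats, cell_barcodes=np.asarray(barcodes, dtype=object),
                            modality_names=list(modality_names), bins=bins.subset(selected),
                            batch_labels=np.asarray(batch_labels, dtype=object),
                            cell_type_labels=cell_type_labels)


def bin_fragment_files(fragment_paths, modality_names, chrom_sizes_path,
                       bin_width: int = 10_000, blacklist_path=None,
                       n_top: int | None = 25_000, batch_labels=None) -> MultimodalTensor:
    """End-to-end: fragment files -> MultimodalTensor.

    Barcodes are the intersection-checked union: every barcode must be
    present in all modalities (cells measured in all channels).
    """
    sizes_df = pd.read_csv(chrom_sizes_path, sep="\t", header=None, names=["chrom", "length"])
    bins = make_genome_bins(list(sizes_df.itertuples(index=False, name=None)), bin_width)
    if blacklist_path is not None:
        bins = filter_blacklist(bins, BlacklistRegions.from_bed(blacklist_path))
    per_mod_barcodes = []
    frag_lists = []
    for path in fragment_paths:
        frags = list(read_fragments(path))
        frag_lists.append(frags)
        per_mod_barcodes.append({f.barcode for f in frags})
    common = set.intersection(*per_mod_barcodes)
    asym = [len(b - common) for b in per_mod_barcodes]
    if any(asym):
        logger.warning("barcode sets differ across modalities; dropping %s "
                       "modality-private barcodes", asym)
    barcodes = sorted(common)
    mats = [count_fragments(frags, bins, barcodes) for frags in frag_lists]
    if n_top is None:
        selected = np.arange(len(bins))
    else:
        selected = select_top_bins(mats, min(n_top, len(bins)))
    if batch_labels is None:
        batch_labels = np.array(["batch0"] * len(barcodes), dtype=object)
    return assemble_tensor(mats, bins, selected, barcodes, batch_labels,
                           modality_names=modality_names)
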