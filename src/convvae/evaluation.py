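"""Embedding-quality and integration metrics.

Batch-effect removal: ASW (Batch), graph connectivity, graph iLISI and
kBET; biological conservation: ASW (Cell type), NMI and graph cLISI. The
overall integration score weights the two groups at 0.4 and 0.6. LISI is
computed in embedding space with a Gaussian kernel calibrated to a fixed
perplexity (the original LISI convention, median-aggregated); kBET is a
chi-square test of each cell's k0-neighborhood batch composition against
its cell type's global composition.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field

import igraph
import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.stats import chi2
from sklearn.metrics import (
    adjusted_rand_score,
    normalized_mutual_info_score,
    silhouette_samples,
)
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "ClusteringResult",
    "MetricReport",
    "knn_graph",
    "louvain_sweep",
    "ari",
    "nmi",
    "asw_celltype",
    "asw_batch",
    "graph_connectivity",
    "lisi_scores",
    "graph_ilisi",
    "graph_clisi",
    "kbet_acceptance",
    "overall_score",
    "evaluate_embedding",
]


@dataclass
class ClusteringResult:
    resolution: float
    assignments: np.ndarray
    n_clusters: int
    quality: float  # modularity of the best restart


@dataclass
class MetricReport:
    asw_batch: float
    graph_connectivity: float
    graph_ilisi: float
    kbet: float
    asw_celltype: float
    nmi: float
    graph_clisi: float
    overall: float = field(default=None)

    def __post_init__(self):
        if self.overall is None:
            self.overall = overall_score(self)

    def batch_metrics(self):
        return [self.asw_batch, self.graph_connectivity, self.graph_ilisi, self.kbet]

    def bio_metrics(self):
        return [self.asw_celltype, self.nmi, self.graph_clisi]

    def to_dict(self):
        return {k: float(getattr(self, k)) for k in
                ("asw_batch", "graph_connectivity", "graph_ilisi", "kbet",
                 "asw_celltype", "nmi", "graph_clisi", "overall")}


def knn_graph(embeddings: np.ndarray, k: int = 20) -> sp.csr_matrix:
    """Exact Euclidean kNN adjacency, union-symmetrized, self excluded."""
    emb = np.asarray(embeddings, dtype=np.float64)
    n = emb.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of points {n}")
    nbrs = NearestNeighbors(n_neighbors=k + 1, algorithm="auto").fit(emb)
    _, idx = nbrs.kneighbors(emb)
    rows = np.repeat(np.arange(n), k)
    cols = idx[:, 1:].ravel()  # first neighbor is self
    adj = sp.coo_matrix((np.ones(n * k), (rows, cols)), shape=(n, n)).tocsr()
    adj = adj.maximum(adj.T)  # union symmetrization
    adj.data[:] = 1.0
    return adj


def _graph_from_adjacency(adj: sp.csr_matrix) -> igraph.Graph:
    coo = sp.triu(adj, k=1).tocoo()
    g = igraph.Graph(n=adj.shape[0], edges=list(zip(coo.row, coo.col)))
    return g


def louvain_sweep(embeddings, resolutions, n_starts: int = 5, seed: int = 0,
                  k: int = 20) -> list[ClusteringResult]:
    """Louvain over a resolution range; best modularity of n_starts restarts."""
    adj = knn_graph(np.asarray(embeddings), k=k)
    g = _graph_from_adjacency(adj)
    results = []
    for res in resolutions:
        best = None
        for start in range(n_starts):
            igraph.set_random_number_generator(random.Random(seed * 1000 + start))
            part = g.community_multilevel(resolution=float(res))
            quality = part.modularity
            if best is None or quality > best[0]:
                best = (quality, np.asarray(part.membership))
        results.append(ClusteringResult(resolution=float(res), assignments=best[1],
                                        n_clusters=len(np.unique(best[1])),
                                        quality=float(best[0])))
    return results


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index between two partitions."""
    return float(adjusted_rand_score(labels_a, labels_b))


def nmi(labels_a, labels_b) -> float:
    """Normalized mutual information, arithmetic-mean normalization."""
    return float(normalized_mutual_info_score(labels_a, labels_b,
                                              average_method="arithmetic"))


def asw_celltype(embeddings, cell_types) -> float:
    """(mean silhouette + 1) / 2 with cell-type labels; 1 = well separated."""
    s = silhouette_samples(np.asarray(embeddings), np.asarray(cell_types))
    return float((s.mean() + 1.0) / 2.0)


def asw_batch(embeddings, batches, cell_types) -> float:
    """Batch-mixing silhouette: per type, mean 1 - |s_batch|; 1 = mixed."""
    emb = np.asarray(embeddings)
    batches = np.asarray(batches)
    cell_types = np.asarray(cell_types)
    scores = []
    for ct in np.unique(cell_types):
        mask = cell_types == ct
        if len(np.unique(batches[mask])) < 2:
            warnings.warn(f"cell type {ct!r} has a single batch; skipped in ASW(batch)")
            continue
        s = silhouette_samples(emb[mask], batches[mask])
        scores.append(float(np.mean(1.0 - np.abs(s))))
    if not scores:
        raise ValueError("no cell type with >= 2 batches")
    return float(np.mean(scores))


def graph_connectivity(adjacency: sp.csr_matrix, cell_types) -> float:
    """Per type, fraction of its cells in the largest type-restricted component."""
    cell_types = np.asarray(cell_types)
    scores = []
    for ct in np.unique(cell_types):
        idx = np.flatnonzero(cell_types == ct)
        if len(idx) == 0:
            continue
        sub = adjacency[np.ix_(idx, idx)]
        n_comp, labels = connected_components(sub, directed=False)
        largest = np.bincount(labels).max()
        scores.append(largest / len(idx))
    return float(np.mean(scores))


def lisi_scores(embeddings, labels, perplexity: float = 30.0) -> np.ndarray:
    """Per-cell inverse Simpson index of label probabilities.

    Neighborhood weights use a Gaussian kernel whose bandwidth is
    calibrated per cell (binary search) so the entropy equals
    log(perplexity), over the 3*perplexity nearest neighbors.
    """
    emb = np.asarray(embeddings, dtype=np.float64)
    labels = np.asarray(labels)
    n = emb.shape[0]
    k = min(int(3 * perplexity), n - 1)
    if n <= 3:
        raise ValueError("need more than 3 cells for LISI")
    nbrs = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    dist, idx = nbrs.kneighbors(emb)
    dist, idx = dist[:, 1:], idx[:, 1:]
    uniq, enc = np.unique(labels, return_inverse=True)
    target = np.log(perplexity)
    out = np.empty(n)
    for i in range(n):
        d2 = dist[i] ** 2
        lo, hi = 1e-10, 1e10
        beta = 1.0
        for _ in range(64):
            w = np.exp(-beta * (d2 - d2.min()))
            sw = w.sum()
            p = w / sw
            h = -(p * np.log(np.maximum(p, 1e-300))).sum()
            if abs(h - target) < 1e-5:
                break
            if h > target:
                lo = beta
                beta = beta * 2 if hi >= 1e10 else (beta + hi) / 2
            else:
                hi = beta
                beta = (lo + beta) / 2
        probs = np.bincount(enc[idx[i]], weights=p, minlength=len(uniq))
        out[i] = 1.0 / np.sum(probs ** 2)
    return out


def graph_ilisi(embeddings, batches, perplexity: float = 30.0) -> float:
    """Median batch LISI rescaled to [0, 1]: 1 = perfectly mixed batches."""
    n_batches = len(np.unique(batches))
    if n_batches < 2:
        raise ValueError("need >= 2 batches for iLISI")
    lisi = lisi_scores(embeddings, batches, perplexity)
    return float(np.clip((np.median(lisi) - 1.0) / (n_batches - 1.0), 0.0, 1.0))


def graph_clisi(embeddings, cell_types, perplexity: float = 30.0) -> float:
    """Rescaled median cell-type LISI: 1 = types fully separated."""
    c = len(np.unique(cell_types))
    if c < 2:
        raise ValueError("need >= 2 cell types for cLISI")
    lisi = lisi_scores(embeddings, cell_types, perplexity)
    return float(np.clip((c - np.median(lisi)) / (c - 1.0), 0.0, 1.0))


def kbet_acceptance(embeddings, batches, cell_types, k0: int = 50,
                    alpha: float = 0.05) -> float:
    """Mean chi-square acceptance rate of local vs global batch composition.

    Per cell type, each cell's k0-neighborhood batch counts are tested
    against the type's global batch proportions (Pearson chi-square,
    B - 1 degrees of freedom); the score is the mean over types of the
    fraction of cells with p > alpha. Types with <= k0 cells are skipped.
    """
    emb = np.asarray(embeddings, dtype=np.float64)
    batches = np.asarray(batches)
    cell_types = np.asarray(cell_types)
    levels = np.unique(batches)
    if len(levels) < 2:
        raise ValueError("need >= 2 batches for kBET")
    enc = np.searchsorted(levels, batches)
    rates = []
    for ct in np.unique(cell_types):
        idx = np.flatnonzero(cell_types == ct)
        if len(idx) <= k0:
            warnings.warn(f"cell type {ct!r} has <= k0 cells; skipped in kBET")
            continue
        sub_emb, sub_b = emb[idx], enc[idx]
        global_prop = np.bincount(sub_b, minlength=len(levels)) / len(idx)
        nbrs = NearestNeighbors(n_neighbors=k0).fit(sub_emb)
        _, nb_idx = nbrs.kneighbors(sub_emb)
        expected = global_prop * k0
        ok = expected > 0
        observed = np.stack([np.bincount(sub_b[row], minlength=len(levels))
                             for row in nb_idx])
        stat = ((observed[:, ok] - expected[ok]) ** 2 / expected[ok]).sum(axis=1)
        pvals = chi2.sf(stat, df=ok.sum() - 1)
        rates.append(float(np.mean(pvals > alpha)))
    if not rates:
        raise ValueError("no cell type larger than k0")
    return float(np.mean(rates))


def overall_score(report: "MetricReport") -> float:
    """0.4 * mean(batch metrics) + 0.6 * mean(bio metrics)."""
    return float(0.4 * np.mean(report.batch_metrics())
                 + 0.6 * np.mean(report.bio_metrics()))


def evaluate_embedding(embeddings, batches, cell_types, k: int = 20,
                       resolutions=None, n_starts: int = 5, seed: int = 0,
                       perplexity: float = 30.0, kbet_k0: int = 50) -> MetricReport:
    """Compute the full metric panel for one embedding.

    NMI is reported at the resolution of the sweep that maximizes it
    (the sweep defaults to 0.2..2.0 in steps of 0.2).
    """
    emb = np.asarray(embeddings, dtype=np.float64)
    cell_types = np.asarray(cell_types)
    if resolutions is None:
        resolutions = np.round(np.arange(0.2, 2.01, 0.2), 2)
    min_type = min(np.bincount(np.unique(cell_types, return_inverse=True)[1]))
    if kbet_k0 >= min_type:
        kbet_k0 = max(min_type - 1, 10)
        warnings.warn(f"kBET k0 capped at {kbet_k0} (smallest cell type has "
                      f"{min_type} cells)")
    max_perp = (emb.shape[0] - 1) / 3
    if perplexity > max_perp:
        perplexity = max(max_perp, 5.0)
        warnings.warn(f"LISI perplexity capped at {perplexity:.0f} for "
                      f"{emb.shape[0]} cells")
    adj = knn_graph(emb, k=k)
    sweep = louvain_sweep(emb, resolutions, n_starts=n_starts, seed=seed, k=k)
    best_nmi = max(nmi(cell_types, r.assignments) for r in sweep)
    return MetricReport(
        asw_batch=asw_batch(emb, batches, cell_types),
        graph_connectivity=graph_connectivity(adj, cell_types),
        graph_ilisi=graph_ilisi(emb, batches, perplexity=perplexity),
        kbet=kbet_acceptance(emb, batches, cell_types, k0=kbet_k0),
        asw_celltype=asw_celltype(emb, cell_types),
        nmi=best_nmi,
        graph_clisi=graph_clisi(emb, cell_types, perplexity=perplexity),
    )
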