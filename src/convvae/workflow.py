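"""Benchmark orchestration: repeated training runs, cross-validation folds.

`run_benchmark` follows the comparison protocol: each requested model
variant is trained on the full dataset with several random
initializations, the metric panel is computed per run, and the table
reports mean and SD per metric plus the weighted overall score. A
five-fold cross-validation mode reports Louvain ARI and the
importance-sampled marginal log-likelihood on held-out folds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import MultimodalTensor
from .evaluation import ari, evaluate_embedding, louvain_sweep
from .models_conv import ConvNetVAE
from .models_fc import PoEFcVAE

logger = logging.getLogger(__name__)

__all__ = ["crossval_split", "run_benchmark", "crossval_benchmark", "make_model"]


def crossval_split(n_cells: int, n_folds: int = 5, seed: int = 0) -> list[np.ndarray]:
    """Disjoint, exhaustive, near-equal folds from a seeded shuffle."""
    if n_cells < n_folds:
        raise ValueError("need at least one cell per fold")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_cells)
    return [np.sort(f) for f in np.array_split(order, n_folds)]


def make_model(variant: dict, seed: int = 0):
    """Instantiate a model from a flat variant description.

    ``variant`` holds ``model: conv|fc`` plus estimator keyword
    arguments (kernel, stride, layers, epochs, ...).
    """
    kind = variant.get("model", "conv")
    kwargs = {k: v for k, v in variant.items() if k not in ("model", "name")}
    if kind == "conv":
        return ConvNetVAE(seed=seed, **kwargs)
    if kind == "fc":
        return PoEFcVAE(seed=seed, **kwargs)
    raise ValueError(f"unknown model kind {kind!r}")


def _subset(tensor: MultimodalTensor, rows: np.ndarray) -> MultimodalTensor:
    return MultimodalTensor(
        counts=[c[rows] for c in tensor.counts],
        cell_barcodes=tensor.cell_barcodes[rows],
        modality_names=tensor.modality_names,
        bins=tensor.bins,
        batch_labels=tensor.batch_labels[rows],
        cell_type_labels=None if tensor.cell_type_labels is None
        else tensor.cell_type_labels[rows])


def run_benchmark(tensor: MultimodalTensor, variants: list[dict], n_seeds: int = 5,
                  seed: int = 0, resolutions=None, knn_k: int = 20,
                  log_path: str | Path | None = None) -> pd.DataFrame:
    """Train each variant with n_seeds inits; report metric mean and SD.

    Returns a tidy DataFrame: one row per (variant, seed) plus the
    per-variant mean/SD aggregate rows (column ``aggregate``).
    """
    if tensor.cell_type_labels is None:
        raise ValueError("benchmark needs cell_type_labels on the tensor")
    log_fh = open(log_path, "a") if log_path else None
    rows = []
    for variant in variants:
        name = variant.get("name") or variant.get("model", "conv")
        for s in range(n_seeds):
            run_seed = seed + 101 * s
            model = make_model(variant, seed=run_seed)
            model.fit(tensor)
            emb = model.transform(tensor)
            report = evaluate_embedding(emb, tensor.batch_labels,
                                        tensor.cell_type_labels, k=knn_k,
                                        resolutions=resolutions, seed=run_seed)
            row = {"variant": name, "seed": run_seed, "aggregate": "",
                   "final_loss": model.loss_history_[-1],
                   "n_parameters": model.n_parameters_, **report.to_dict()}
            rows.append(row)
            if log_fh:
                log_fh.write(json.dumps(row) + "\n")
            logger.info("variant %s seed %d overall=%.3f", name, run_seed,
                        report.overall)
    df = pd.DataFrame(rows)
    metric_cols = [c for c in df.columns if c not in
                   ("variant", "seed", "aggregate", "n_parameters")]
    aggs = []
    for name, grp in df.groupby("variant", sort=False):
        mean = grp[metric_cols].mean().to_dict()
        sd = grp[metric_cols].std(ddof=1).to_dict()
        aggs.append({"variant": name, "seed": -1, "aggregate": "mean",
                     "n_parameters": grp["n_parameters"].iloc[0], **mean})
        aggs.append({"variant": name, "seed": -1, "aggregate": "sd",
                     "n_parameters": grp["n_parameters"].iloc[0], **sd})
    if log_fh:
        log_fh.close()
    return pd.concat([df, pd.DataFrame(aggs)], ignore_index=True)


def crossval_benchmark(tensor: MultimodalTensor, variants: list[dict],
                       n_folds: int = 5, seed: int = 0, resolutions=None,
                       n_ll_samples: int = 100, knn_k: int = 20) -> pd.DataFrame:
    """Five-fold protocol: train on folds-1, report held-out ARI and log-lik."""
    folds = crossval_split(tensor.n_cells, n_folds=n_folds, seed=seed)
    all_idx = np.arange(tensor.n_cells)
    if resolutions is None:
        resolutions = [0.4, 0.8, 1.2]
    rows = []
    for variant in variants:
        name = variant.get("name") or variant.get("model", "conv")
        for f, held in enumerate(folds):
            train_idx = np.setdiff1d(all_idx, held)
            model = make_model(variant, seed=seed + f)
            model.fit(_subset(tensor, train_idx))
            val = _subset(tensor, held)
            emb = model.transform(val)
            sweep = louvain_sweep(emb, resolutions, seed=seed + f,
                                  k=min(knn_k, len(held) - 1))
            best_ari = max(ari(val.cell_type_labels, r.assignments) for r in sweep)
            ll = model.log_likelihood(val, n_samples=n_ll_samples, seed=seed + f)
            rows.append({"variant": name, "fold": f, "ari": best_ari,
                         "log_likelihood": ll})
    df = pd.DataFrame(rows)
    agg = df.groupby("variant", sort=False)[["ari", "log_likelihood"]].agg(
        ["mean", "std"])
    agg.columns = ["_".join(c) for c in agg.columns]
    return df, agg.reset_index()
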