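"""Integration metrics against brute-force oracles and constructed cases."""

import itertools
import warnings

import numpy as np
import pytest
from scipy.special import comb

from convvae.evaluation import (
    MetricReport,
    ari,
    asw_batch,
    asw_celltype,
    evaluate_embedding,
    graph_clisi,
    graph_connectivity,
    graph_ilisi,
    kbet_acceptance,
    knn_graph,
    lisi_scores,
    louvain_sweep,
    nmi,
    overall_score,
)


def two_blobs(n_per=60, sep=12.0, d=4, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, size=(n_per, d))
    b = rng.normal(0, 1, size=(n_per, d))
    b[:, 0] += sep
    emb = np.vstack([a, b])
    labels = np.array(["A"] * n_per + ["B"] * n_per)
    return emb, labels


class TestKnnGraph:
    def test_three_collinear_points(self):
        emb = np.array([[0.0], [1.0], [3.0]])
        adj = knn_graph(emb, k=1)
        # middle point links to its nearer neighbor (0); union symmetrization
        assert adj[1, 0] == 1.0
        assert adj[1, 2] == 1.0  # point 2's neighbor is 1 -> symmetrized
        assert adj[0, 2] == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        emb = rng.normal(size=(200, 5))
        k = 7
        adj = knn_graph(emb, k=k)
        d2 = ((emb[:, None, :] - emb[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        expected = np.zeros((200, 200))
        for i in range(200):
            for j in np.argsort(d2[i])[:k]:
                expected[i, j] = 1
        expected = np.maximum(expected, expected.T)
        assert np.array_equal(adj.toarray(), expected)

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            knn_graph(np.zeros((5, 2)), k=5)


class TestLouvain:
    def test_two_blobs_recovered(self):
        emb, labels = two_blobs()
        res = louvain_sweep(emb, [0.5], seed=0)[0]
        assert res.n_clusters == 2
        assert ari(labels, res.assignments) == 1.0

    def test_seeded_determinism(self):
        emb, _ = two_blobs(seed=2)
        a = louvain_sweep(emb, [0.8, 1.2], seed=5)
        b = louvain_sweep(emb, [0.8, 1.2], seed=5)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.assignments, rb.assignments)

    def test_cluster_count_nondecreasing_with_resolution(self):
        rng = np.random.default_rng(0)
        emb = rng.normal(size=(150, 3))
        sweep = louvain_sweep(emb, [0.2, 3.0], n_starts=5, seed=1)
        assert sweep[0].n_clusters <= sweep[1].n_clusters


def pair_counting_ari(a, b):
    """Brute-force ARI via pair counting over all unordered pairs."""
    n = len(a)
    n11 = n00 = n10 = n01 = 0
    for i, j in itertools.combinations(range(n), 2):
        sa, sb = a[i] == a[j], b[i] == b[j]
        n11 += sa and sb
        n00 += (not sa) and (not sb)
        n10 += sa and not sb
        n01 += (not sa) and sb
    total = comb(n, 2)
    expected = (n11 + n10) * (n11 + n01) / total
    maximum = ((n11 + n10) + (n11 + n01)) / 2
    if maximum == expected:
        return 1.0
    return (n11 - expected) / (maximum - expected)


def entropy_nmi(a, b):
    """Information-theoretic NMI with arithmetic-mean normalization."""
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)

    def H(x):
        _, counts = np.unique(x, return_counts=True)
        p = counts / n
        return -(p * np.log(p)).sum()

    mi = 0.0
    for ua in np.unique(a):
        for ub in np.unique(b):
            pab = np.mean((a == ua) & (b == ub))
            if pab > 0:
                mi += pab * np.log(pab / (np.mean(a == ua) * np.mean(b == ub)))
    denom = (H(a) + H(b)) / 2
    return mi / denom if denom > 0 else 1.0


class TestPartitionScores:
    def test_identical_partitions(self):
        assert ari([0, 0, 1, 1], [1, 1, 0, 0]) == 1.0
        assert nmi([0, 0, 1, 1], [1, 1, 0, 0]) == 1.0

    def test_crossed_partition_value(self):
        assert np.isclose(ari([0, 0, 1, 1], [0, 1, 0, 1]), -0.5)

    def test_matches_pair_counting_oracle_exhaustively(self):
        """All partitions pairs on small label vectors (<= 12 items)."""
        rng = np.random.default_rng(0)
        for _ in range(40):
            n = rng.integers(4, 13)
            a = rng.integers(0, 3, size=n)
            b = rng.integers(0, 4, size=n)
            assert np.isclose(ari(a, b), pair_counting_ari(a, b), atol=1e-12)
            assert np.isclose(nmi(a, b), entropy_nmi(a, b), atol=1e-9)

    def test_singletons_vs_any(self):
        a = np.arange(10)
        b = np.zeros(10, dtype=int)
        assert np.isclose(ari(a, b), pair_counting_ari(a, b))


class TestSilhouetteScores:
    def test_asw_celltype_separated_blobs(self):
        emb, labels = two_blobs(sep=50.0)
        assert asw_celltype(emb, labels) > 0.95

    def test_asw_celltype_random_labels_near_half(self):
        rng = np.random.default_rng(0)
        emb = rng.normal(size=(300, 3))
        labels = rng.integers(0, 2, size=300)
        assert abs(asw_celltype(emb, labels) - 0.5) < 0.05

    def test_asw_batch_mixed_vs_separated(self):
        emb, types = two_blobs(sep=30.0, seed=1)
        rng = np.random.default_rng(2)
        mixed = rng.integers(0, 2, size=len(types)).astype(str)
        assert asw_batch(emb, mixed, types) > 0.9
        separated = np.array(["x"] * 30 + ["y"] * 30 + ["x"] * 30 + ["y"] * 30)
        emb_sep = emb.copy()
        emb_sep[separated == "y", 1] += 40.0
        assert asw_batch(emb_sep, separated, types) < 0.1

    def test_single_batch_type_skipped_with_warning(self):
        emb, types = two_blobs(n_per=20, seed=3)
        batches = np.array(["b0"] * 20 + ["b0"] * 10 + ["b1"] * 10)
        with pytest.warns(UserWarning, match="single batch"):
            asw_batch(emb, batches, types)


class TestGraphConnectivity:
    def test_fully_connected_types(self):
        emb, types = two_blobs(n_per=30)
        adj = knn_graph(emb, k=5)
        assert graph_connectivity(adj, types) == 1.0

    def test_split_type_scores_half(self):
        # one type in two far-apart halves of 10; the other compact
        rng = np.random.default_rng(1)
        a1 = rng.normal(0, 0.1, size=(10, 2))
        a2 = rng.normal(0, 0.1, size=(10, 2)) + [100, 0]
        b = rng.normal(0, 0.1, size=(20, 2)) + [50, 50]
        emb = np.vstack([a1, a2, b])
        types = np.array(["A"] * 20 + ["B"] * 20)
        adj = knn_graph(emb, k=3)
        score = graph_connectivity(adj, types)
        assert np.isclose(score, (0.5 + 1.0) / 2)


class TestLisi:
    def test_single_label_gives_one(self):
        rng = np.random.default_rng(0)
        emb = rng.normal(size=(120, 3))
        lisi = lisi_scores(emb, np.zeros(120, dtype=int), perplexity=20)
        assert np.allclose(lisi, 1.0)

    def test_interleaved_two_labels_near_two(self):
        emb = np.arange(200, dtype=float)[:, None]
        labels = np.arange(200) % 2
        lisi = lisi_scores(emb, labels, perplexity=20)
        assert abs(np.median(lisi) - 2.0) < 0.1

    def test_rescaled_scores_in_unit_interval(self):
        rng = np.random.default_rng(5)
        emb = rng.normal(size=(150, 4))
        batches = rng.integers(0, 3, size=150)
        types = rng.integers(0, 4, size=150)
        assert 0.0 <= graph_ilisi(emb, batches) <= 1.0
        assert 0.0 <= graph_clisi(emb, types) <= 1.0

    def test_separated_batches_low_ilisi(self):
        emb, batches = two_blobs(sep=60.0, seed=4)
        assert graph_ilisi(emb, batches) < 0.05


class TestKbet:
    def test_iid_batches_accept_near_one_minus_alpha(self):
        rng = np.random.default_rng(0)
        emb = rng.normal(size=(600, 4))
        batches = rng.integers(0, 2, size=600)
        types = np.zeros(600, dtype=int)
        rate = kbet_acceptance(emb, batches, types, k0=50, alpha=0.05)
        assert rate > 0.80  # null calibration: close to 1 - alpha

    def test_segregated_batches_rejected(self):
        emb, batches = two_blobs(n_per=100, sep=40.0, seed=1)
        types = np.zeros(200, dtype=int)
        assert kbet_acceptance(emb, batches, types, k0=50) < 0.05

    def test_small_types_skipped(self):
        emb, batches = two_blobs(n_per=30, seed=2)
        types = np.zeros(60, dtype=int)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            with pytest.raises(Exception):
                kbet_acceptance(emb, batches, types, k0=100)


class TestOverallScore:
    @pytest.mark.parametrize("batch_val,bio_val,expected", [
        (1.0, 1.0, 1.0),
        (1.0, 0.0, 0.4),
        (0.5, 1.0, 0.8),
    ])
    def test_weighted_average(self, batch_val, bio_val, expected):
        report = MetricReport(asw_batch=batch_val, graph_connectivity=batch_val,
                              graph_ilisi=batch_val, kbet=batch_val,
                              asw_celltype=bio_val, nmi=bio_val,
                              graph_clisi=bio_val)
        assert np.isclose(report.overall, expected)
        assert np.isclose(overall_score(report), expected)


def test_full_report_in_unit_interval():
    rng = np.random.default_rng(7)
    emb = rng.normal(size=(250, 5))
    batches = rng.integers(0, 2, size=250).astype(str)
    types = np.array(["t0", "t1", "t2"])[rng.integers(0, 3, size=250)]
    report = evaluate_embedding(emb, batches, types, k=15, kbet_k0=30,
                                resolutions=[0.5, 1.0])
    for value in report.to_dict().values():
        assert 0.0 <= value <= 1.0
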