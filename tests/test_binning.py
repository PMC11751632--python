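"""Genome windowing, blacklist filtering, fragment counting, top-bin selection."""

import gzip

import numpy as np
import pytest
import scipy.sparse as sp

from convvae.binning import (
    BlacklistRegions,
    FragmentRecord,
    assemble_tensor,
    bin_fragment_files,
    count_fragments,
    filter_blacklist,
    make_genome_bins,
    read_fragments,
    reads_to_fragments,
    select_top_bins,
)
from convvae.simulate import SimConfig, simulate_dataset, write_fragment_files


class TestMakeGenomeBins:
    def test_truncated_last_bin(self):
        bins = make_genome_bins([("chr1", 25_000)], 10_000)
        assert list(bins.starts) == [0, 10_000, 20_000]
        assert list(bins.ends) == [10_000, 20_000, 25_000]

    def test_exact_multiple(self):
        assert len(make_genome_bins([("chr1", 20_000)], 10_000)) == 2

    def test_two_chromosomes_in_order(self):
        bins = make_genome_bins([("chr1", 30_000), ("chr2", 10_000)], 10_000)
        assert len(bins) == 4
        assert list(bins.chroms) == ["chr1"] * 3 + ["chr2"]

    def test_duplicate_chromosome_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            make_genome_bins([("chr1", 100), ("chr1", 100)], 10)


class TestFilterBlacklist:
    def setup_method(self):
        self.bins = make_genome_bins([("chr1", 30_000)], 10_000)

    def test_overlap_removes_bin(self):
        out = filter_blacklist(self.bins, BlacklistRegions((("chr1", 5000, 6000),)))
        assert list(out.starts) == [10_000, 20_000]

    def test_empty_blacklist_identity(self):
        out = filter_blacklist(self.bins, BlacklistRegions(()))
        assert len(out) == 3

    def test_abutting_interval_keeps_bin(self):
        # half-open: [10000, 11000) does not overlap [0, 10000)
        out = filter_blacklist(self.bins, BlacklistRegions((("chr1", 10_000, 11_000),)))
        assert 0 in out.starts


class TestCountFragments:
    def setup_method(self):
        self.bins = make_genome_bins([("chr1", 30_000)], 10_000)

    def test_fragment_within_one_bin(self):
        mat = count_fragments([FragmentRecord("chr1", 100, 300, "bc1")],
                              self.bins, ["bc1"])
        assert mat[0, 0] == 1 and mat.sum() == 1

    def test_boundary_spanning_fragment_counts_in_both(self):
        mat = count_fragments([FragmentRecord("chr1", 9_900, 10_100, "bc1")],
                              self.bins, ["bc1"])
        assert mat[0, 0] == 1 and mat[0, 1] == 1

    def test_empty_stream(self):
        assert count_fragments([], self.bins, ["bc1"]).sum() == 0

    def test_unknown_barcode_and_chrom_skipped(self):
        mat = count_fragments([FragmentRecord("chr1", 0, 50, "nope"),
                               FragmentRecord("chrX", 0, 50, "bc1")],
                              self.bins, ["bc1"])
        assert mat.sum() == 0

    def test_total_at_least_fragment_total(self):
        frags = [FragmentRecord("chr1", 9_990, 10_010, "bc1", 2),
                 FragmentRecord("chr1", 50, 60, "bc1", 3)]
        mat = count_fragments(frags, self.bins, ["bc1"])
        assert mat.sum() >= sum(f.count for f in frags)


@pytest.mark.parametrize("reads,frags", [(5, 3), (4, 2), (0, 0), (1, 1)])
def test_reads_to_fragments(reads, frags):
    assert reads_to_fragments(reads) == frags


def test_reads_to_fragments_rejects_negative():
    with pytest.raises(ValueError):
        reads_to_fragments(np.array([-1]))


class TestSelectTopBins:
    def test_single_modality_ties_by_index(self):
        mats = [sp.csr_matrix(np.array([[5, 1, 9, 9]]))]
        assert list(select_top_bins(mats, 2)) == [2, 3]

    def test_union_at_smallest_k(self):
        mats = [sp.csr_matrix(np.array([[9, 0, 0, 1]])),
                sp.csr_matrix(np.array([[0, 9, 0, 1]]))]
        assert list(select_top_bins(mats, 2)) == [0, 1]

    def test_n_top_equals_g_returns_all(self):
        mats = [sp.csr_matrix(np.array([[3, 1, 2]]))]
        assert list(select_top_bins(mats, 3)) == [0, 1, 2]

    def test_n_top_too_large_rejected(self):
        with pytest.raises(ValueError):
            select_top_bins([sp.csr_matrix(np.array([[1, 2]]))], 3)

    def test_invariant_to_modality_order(self):
        rng = np.random.default_rng(0)
        mats = [sp.csr_matrix(rng.poisson(2, size=(5, 30))) for _ in range(3)]
        a = select_top_bins(mats, 10)
        b = select_top_bins(mats[::-1], 10)
        assert np.array_equal(a, b)


class TestAssembleTensor:
    def test_known_entries(self):
        bins = make_genome_bins([("chr1", 400)], 100)
        m0 = sp.csr_matrix(np.array([[1, 2, 3, 4], [5, 6, 7, 8]]))
        m1 = sp.csr_matrix(np.array([[0, 1, 0, 1], [2, 0, 2, 0]]))
        t = assemble_tensor([m0, m1], bins, [1, 3], ["a", "b"], ["b0", "b1"])
        assert t.shape == (2, 2, 2)
        assert np.array_equal(t.to_dense()[:, 0, :], [[2, 4], [6, 8]])
        assert np.array_equal(t.to_dense()[:, 1, :], [[1, 1], [0, 0]])

    def test_select_all_is_lossless(self):
        bins = make_genome_bins([("chr1", 300)], 100)
        m0 = sp.csr_matrix(np.array([[1, 0, 2]]))
        t = assemble_tensor([m0], bins, [0, 1, 2], ["a"], ["b0"])
        assert np.array_equal(t.to_dense()[:, 0, :], [[1, 0, 2]])

    def test_cell_count_mismatch_rejected(self):
        bins = make_genome_bins([("chr1", 200)], 100)
        with pytest.raises(ValueError, match="differ"):
            assemble_tensor([sp.csr_matrix(np.zeros((2, 2))),
                             sp.csr_matrix(np.zeros((3, 2)))],
                            bins, [0], ["a", "b"], ["b0", "b0"])


class TestFragmentIO:
    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "frags.tsv"
        path.write_text("chr1\t0\t100\tbc1\t1\nchr1\tnope\t200\tbc1\t1\n")
        with pytest.raises(ValueError, match="frags.tsv:2"):
            list(read_fragments(path))

    def test_gzip_transparent(self, tmp_path):
        path = tmp_path / "frags.tsv.gz"
        with gzip.open(path, "wt") as fh:
            fh.write("chr1\t10\t60\tbc1\t2\n")
        recs = list(read_fragments(path))
        assert recs == [FragmentRecord("chr1", 10, 60, "bc1", 2)]


def test_round_trip_synthetic_fragments(tmp_path):
    """Binning the generator's fragment files reproduces the tensor exactly."""
    cfg = SimConfig(n_cells=30, n_bins=12, n_clusters=2, n_batches=1,
                    peaks_per_cluster=3, library_log_mean=np.log(40.0), seed=5)
    tensor, _ = simulate_dataset(cfg)
    paths = write_fragment_files(tensor, tmp_path, seed=3)
    sizes = tmp_path / "chrom.sizes"
    sizes.write_text("chrSim\t12000\n")
    rebinned = bin_fragment_files(paths, tensor.modality_names, sizes,
                                  bin_width=1000, n_top=None)
    order = np.argsort(tensor.cell_barcodes)
    assert np.array_equal(rebinned.to_dense(),
                          tensor.to_dense()[order])
    assert rebinned.to_dense().sum() == sum(c.sum() for c in tensor.counts)
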