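"""NE normalization identities, QC filtering, over-dispersion selection."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import rgcsub as rs
from rgcsub.io import CountMatrixError, GenePanel
from rgcsub.preprocess import PreprocessError


def make_counts(matrix, eyes=None, genes=None):
    matrix = np.asarray(matrix)
    n, g = matrix.shape
    eyes = eyes or ["unknown"] * n
    genes = genes or [f"g{j}" for j in range(g)]
    return ad.AnnData(
        X=sp.csr_matrix(matrix.astype(np.int32)),
        obs=pd.DataFrame(
            {"eye": pd.Categorical(eyes, categories=["left", "right", "unknown"])},
            index=[f"c{i}" for i in range(n)],
        ),
        var=pd.DataFrame(index=genes),
    )


class TestNormalizeNE:
    def test_two_cell_worked_example(self):
        """Totals 100 and 200 -> M = 150; count 10 in the 100-total cell
        gives NE = log2(10 * 150/100 + 1) = log2(16) = 4 exactly."""
        row1 = np.zeros(20, dtype=int)
        row1[0] = 10
        row1[1:10] = 10  # fill to total 100
        row2 = np.zeros(20, dtype=int)
        row2[10:] = 20  # total 200
        cm = make_counts(np.vstack([row1, row2]))
        ne = rs.normalize_ne(cm)
        assert ne.uns["ne"]["M"] == 150.0
        assert ne.X[0, 0] == pytest.approx(4.0, abs=1e-12)

    def test_zero_count_maps_to_zero(self):
        cm = make_counts([[0, 5], [3, 2]])
        ne = rs.normalize_ne(cm)
        assert ne.X[0, 0] == 0.0

    def test_zero_total_cell_named_in_error(self):
        cm = make_counts([[0, 0], [3, 2]])
        with pytest.raises(PreprocessError, match="c0"):
            rs.normalize_ne(cm)

    def test_within_cell_rank_preservation(self):
        rng = np.random.default_rng(0)
        cm = make_counts(rng.integers(0, 50, size=(50, 20)) + (np.arange(20) == 0))
        ne = rs.normalize_ne(cm)
        X = np.asarray(cm.X.todense())
        N = np.asarray(ne.X.todense())
        for i in range(50):
            assert (np.argsort(X[i], kind="stable") == np.argsort(N[i], kind="stable")).all()

    def test_ne_invariants_hypothesis(self):
        """Zeros map to zero and within-cell ranking is preserved for any
        non-degenerate count matrix."""
        from hypothesis import given, settings, strategies as st
        from hypothesis.extra.numpy import arrays

        @settings(max_examples=50, deadline=None, derandomize=True)
        @given(arrays(np.int32, (6, 8), elements=st.integers(0, 100)))
        def check(counts):
            if (counts.sum(axis=1) == 0).any():
                return
            ne = rs.normalize_ne(make_counts(counts))
            N = np.asarray(ne.X.todense())
            assert ((counts == 0) == (N == 0)).all()
            for i in range(counts.shape[0]):
                assert (np.argsort(counts[i], kind="stable")
                        == np.argsort(N[i], kind="stable")).all()

        check()

    def test_matches_scanpy_median_normalization(self):
        """Independent oracle: scanpy's median library-size normalization
        followed by a base-2 log1p reproduces NE exactly."""
        scanpy = pytest.importorskip("scanpy")
        rng = np.random.default_rng(1)
        counts = rng.poisson(1.2, size=(40, 30)).astype(np.int32)
        counts[:, 0] += 1  # no zero-total cells
        cm = make_counts(counts)
        ne = rs.normalize_ne(cm)
        ref = cm.copy()
        scanpy.pp.normalize_total(ref, target_sum=None)
        scanpy.pp.log1p(ref, base=2)
        np.testing.assert_allclose(
            np.asarray(ne.X.todense()), np.asarray(ref.X.todense()), atol=1e-9
        )

    def test_sequencing_depth_invariance(self):
        """Scaling one cell's library by an integer factor leaves x*M/T for
        that cell unchanged exactly (M is set by the median cell), so its NE
        row is identical — the point of median-ratio normalization."""
        rng = np.random.default_rng(2)
        counts = rng.poisson(2.0, size=(21, 15)).astype(np.int32)
        counts[:, 0] += 1
        totals = counts.sum(axis=1)
        cell = int(np.argmax(totals))  # scaling the max cell keeps M fixed
        scaled = counts.copy()
        scaled[cell] *= 3
        ne1 = rs.normalize_ne(make_counts(counts))
        ne2 = rs.normalize_ne(make_counts(scaled))
        assert ne1.uns["ne"]["M"] == ne2.uns["ne"]["M"]
        np.testing.assert_allclose(
            np.asarray(ne1.X.todense())[cell], np.asarray(ne2.X.todense())[cell],
            atol=1e-9,
        )


class TestFilterLowCoverage:
    def test_boundary_cell_removed(self):
        m = np.zeros((2, 5), dtype=int)
        m[0, :4] = 1  # 4 genes detected
        m[1, :] = 1  # 5 genes detected
        cm = make_counts(m)
        kept, removed = rs.filter_low_coverage(cm, min_genes=5)
        assert removed == ["c0"]
        assert kept.n_obs == 1

    def test_zero_cutoff_is_identity(self):
        cm = make_counts([[1, 0], [0, 2]])
        kept, removed = rs.filter_low_coverage(cm, min_genes=0)
        assert kept.n_obs == 2 and removed == []

    def test_all_removed_raises(self):
        cm = make_counts([[1, 0], [0, 2]])
        with pytest.raises(PreprocessError):
            rs.filter_low_coverage(cm, min_genes=3)

    def test_removal_rate_matches_planted(self, desk_sim):
        cfg, counts, truth = desk_sim
        _, removed = rs.filter_low_coverage(counts, rs.simulate.DESK_QC_MIN_GENES)
        rate = len(removed) / counts.n_obs
        assert rate == pytest.approx(cfg.low_quality_fraction, abs=0.02)

    def test_filter_then_normalize_changes_m(self, desk_sim):
        _, counts, _ = desk_sim
        filtered, _ = rs.filter_low_coverage(counts, rs.simulate.DESK_QC_MIN_GENES)
        m_all = rs.normalize_ne(counts).uns["ne"]["M"]
        m_filtered = rs.normalize_ne(filtered).uns["ne"]["M"]
        assert m_filtered != m_all  # pipeline order (filter first) matters


class TestSelectOverdispersed:
    def test_constant_gene_never_selected(self):
        m = np.ones((30, 3), dtype=int)
        m[:15, 1] = 5  # variable gene
        m[:, 2] = [1, 9] * 15  # variable gene
        genes = rs.select_overdispersed(rs.normalize_ne(make_counts(m)), n=2)
        assert "g0" not in genes

    def test_excluded_panel_absent(self):
        m = np.ones((30, 3), dtype=int)
        m[:15, 0] = 40  # most dispersed by far
        m[:10, 1] = 5
        ne = rs.normalize_ne(make_counts(m))
        panel = GenePanel("sex", ("g0",), "sex")
        genes = rs.select_overdispersed(ne, n=2, exclude=panel)
        assert "g0" not in genes

    def test_warns_when_fewer_eligible(self):
        m = np.ones((10, 3), dtype=int)
        m[:5, 1] = 3
        ne = rs.normalize_ne(make_counts(m))
        with pytest.warns(UserWarning, match="eligible"):
            genes = rs.select_overdispersed(ne, n=50)
        assert len(genes) == 3

    def test_planted_structure_ranks_high(self, qc_ne, desk_sim, panels):
        _, _, truth = desk_sim
        genes = set(rs.select_overdispersed(qc_ne, n=1000, exclude=panels["sex"]))
        pair_selected = sum(1 for g in genes if g.startswith("Pair"))
        assert pair_selected >= 250  # separation program dominates dispersion
        assert not any(g in genes for g in panels["sex"].genes)


class TestReadCounts:
    def test_toy_mtx_roundtrip(self, tmp_path):
        mtx = tmp_path / "m.mtx"
        mtx.write_text(
            "%%MatrixMarket matrix coordinate integer general\n3 2 1\n1 1 5\n"
        )
        (tmp_path / "genes.tsv").write_text("ga\ngb\ngc\n")
        (tmp_path / "bc.tsv").write_text("b1\tleft\nb2\tright\n")
        cm = rs.read_counts(mtx, tmp_path / "genes.tsv", tmp_path / "bc.tsv")
        assert cm.shape == (2, 3)
        assert cm.X[0, 0] == 5 and cm.X.sum() == 5
        assert cm.obs["eye"].tolist() == ["left", "right"]

    def test_barcode_mismatch_raises(self, tmp_path):
        mtx = tmp_path / "m.mtx"
        mtx.write_text("%%MatrixMarket matrix coordinate integer general\n3 2 1\n1 1 5\n")
        (tmp_path / "genes.tsv").write_text("ga\ngb\ngc\n")
        (tmp_path / "bc.tsv").write_text("b1\tleft\n")
        with pytest.raises(CountMatrixError, match="mismatch"):
            rs.read_counts(mtx, tmp_path / "genes.tsv", tmp_path / "bc.tsv")

    def test_transposed_matrix_rejected(self, tmp_path):
        mtx = tmp_path / "m.mtx"
        mtx.write_text("%%MatrixMarket matrix coordinate integer general\n2 3 1\n1 1 5\n")
        (tmp_path / "genes.tsv").write_text("ga\ngb\ngc\n")
        (tmp_path / "bc.tsv").write_text("b1\tleft\nb2\tright\n")
        with pytest.raises(CountMatrixError, match="transposed"):
            rs.read_counts(mtx, tmp_path / "genes.tsv", tmp_path / "bc.tsv")

    def test_duplicate_barcodes_rejected(self, tmp_path):
        mtx = tmp_path / "m.mtx"
        mtx.write_text("%%MatrixMarket matrix coordinate integer general\n3 2 1\n1 1 5\n")
        (tmp_path / "genes.tsv").write_text("ga\ngb\ngc\n")
        (tmp_path / "bc.tsv").write_text("b1\tleft\nb1\tright\n")
        with pytest.raises(CountMatrixError, match="barcode"):
            rs.read_counts(mtx, tmp_path / "genes.tsv", tmp_path / "bc.tsv")
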