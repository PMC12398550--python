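"""QC, normalisation, variable genes, PCA, elbow, and Louvain clustering."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from oligomap import preprocess
from oligomap.errors import EmptyResultError, ValidationError
from oligomap.preprocess import (
    Embedding,
    QCConfig,
    choose_elbow,
    cluster_cells,
    filter_cells,
    filter_genes,
    modularity,
    normalize,
    run_pca,
    select_variable_genes,
    size_factors,
)

from .conftest import make_count_matrix


class TestGeneFilter:
    @pytest.mark.parametrize("n_detected,kept", [(10, False), (11, True)])
    def test_ten_cell_boundary(self, n_detected, kept):
        """A gene seen in exactly 10 cells is removed; in 11 it survives."""
        dense = np.zeros((2, 20), dtype=int)
        dense[0, :n_detected] = 1
        dense[1, :] = 5  # keeps the matrix non-empty
        m = make_count_matrix(dense)
        out = filter_genes(m)
        assert ("G0" in out.gene_ids) is kept

    def test_threshold_zero_keeps_any_detected_gene(self):
        dense = np.array([[1] + [0] * 19, [0] * 20])
        m = make_count_matrix(dense)
        out = filter_genes(m, QCConfig(min_cells_per_gene_exclusive=0))
        assert list(out.gene_ids) == ["G0"]

    def test_all_removed_raises(self):
        m = make_count_matrix(np.ones((3, 2), dtype=int))
        with pytest.raises(EmptyResultError):
            filter_genes(m)

    def test_filter_is_idempotent(self, reference):
        m, _, _ = reference
        once = filter_genes(m)
        twice = filter_genes(once)
        assert once == twice


class TestCellFilter:
    def test_homogeneous_cells_nearly_all_kept(self):
        """With no planted outliers the 3-MAD rule removes at most 1% of cells."""
        from oligomap.simulate import SimulationConfig, simulate_reference

        cfg = SimulationConfig(n_classes=1, n_genes=300, cells_per_class=400,
                               markers_per_class=0, seed=21)
        m, _, _ = simulate_reference(cfg)
        out, report = filter_cells(m)
        assert report["removed"].mean() <= 0.01

    def test_high_mito_cell_removed_and_attributed(self):
        rng = np.random.default_rng(0)
        dense = rng.poisson(5, size=(10, 30))
        dense[0] = 1  # mito gene low everywhere
        dense[0, 0] = dense[1:, 0].sum() * 9  # cell 0: 90% mito
        m = make_count_matrix(dense, gene_ids=["MT-CO1"] + [f"G{i}" for i in range(1, 10)])
        qc = QCConfig(max_mito_fraction=0.2, mad_multiplier=100.0)
        out, report = filter_cells(m, qc)
        assert report.loc[0, "fail_mito"] and report.loc[0, "removed"]
        assert "C0" not in out.barcodes

    def test_huge_mad_leaves_only_mito_criterion(self):
        rng = np.random.default_rng(1)
        m = make_count_matrix(rng.poisson(5, size=(5, 40)))
        _, report = filter_cells(m, QCConfig(mad_multiplier=1e6, max_mito_fraction=0.5))
        assert not report["fail_umi"].any() and not report["fail_gene_count"].any()

    def test_mass_removal_escalates(self):
        # all library sizes distinct -> a zero-width MAD band removes everything
        dense = (np.arange(1, 11) * 100)[None, :]
        m = make_count_matrix(dense)
        with pytest.raises(EmptyResultError):
            filter_cells(m, QCConfig(mad_multiplier=0.0))
        # unless explicitly forced
        out, report = filter_cells(m, QCConfig(mad_multiplier=0.0), force=True)
        assert report["removed"].all()


class TestNormalize:
    def test_equal_libraries_give_unit_factors(self):
        m = make_count_matrix(np.full((4, 5), 3))
        assert np.allclose(size_factors(m), 1.0)

    def test_doubled_cell_has_doubled_factor(self):
        col = np.array([3, 1, 4, 2])
        m = make_count_matrix(np.column_stack([col, 2 * col]))
        sf = size_factors(m)
        assert sf[1] / sf[0] == pytest.approx(2.0)

    def test_geometric_mean_is_one(self, reference):
        m, _, _ = reference
        sf = size_factors(filter_genes(m))
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0)

    def test_zero_count_cell_rejected(self):
        dense = np.array([[1, 0], [2, 0]])
        with pytest.raises(ValidationError):
            normalize(make_count_matrix(dense))

    def test_normalisation_shrinks_total_cv(self):
        """Depth correction reduces the coefficient of variation of cell totals."""
        rng = np.random.default_rng(7)
        depth = rng.uniform(0.5, 2.0, size=100)
        dense = rng.poisson(np.outer(np.full(50, 3.0), depth))
        dense[:, dense.sum(axis=0) == 0] += 1
        m = make_count_matrix(dense)
        nm = normalize(m)
        raw_tot = dense.sum(axis=0)
        norm_tot = np.expm1(nm.values).sum(axis=0)
        cv = lambda x: x.std() / x.mean()
        assert cv(norm_tot) < cv(raw_tot)


class TestVariableGenes:
    def test_constant_gene_never_selected(self):
        rng = np.random.default_rng(0)
        dense = rng.poisson(2, size=(10, 50))
        dense[0] = 4  # constant gene
        nm = normalize(make_count_matrix(dense))
        assert "G0" not in select_variable_genes(nm, 5)

    def test_markers_dominate_top_set(self, reference, small_cfg):
        m, _, _ = reference
        nm = normalize(filter_genes(m))
        top = select_variable_genes(nm, 60)
        n_markers = small_cfg.n_classes * small_cfg.markers_per_class
        markers = {f"G{i:05d}" for i in range(n_markers)}
        assert len(markers & set(top)) / n_markers >= 0.9

    def test_n_top_equal_gene_count_returns_all(self, reference):
        m, _, _ = reference
        nm = normalize(filter_genes(m))
        assert set(select_variable_genes(nm, nm.n_genes)) == set(nm.gene_ids)

    def test_constant_matrix_rejected(self):
        nm = normalize(make_count_matrix(np.full((4, 5), 2)))
        with pytest.raises(ValidationError):
            select_variable_genes(nm, 2)


class TestPCA:
    def test_rank_three_data_has_no_variance_beyond_pc3(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(3, 30))
        mix = rng.normal(size=(20, 3)) @ base  # genes x cells, rank 3
        nm = preprocess.NormalizedMatrix(
            values=mix, size_factors=np.ones(30),
            gene_ids=[f"G{i}" for i in range(20)], barcodes=[f"C{j}" for j in range(30)],
        )
        emb = run_pca(nm, list(nm.gene_ids), max_pcs=10, scale=False)
        total = emb.explained_variance.sum()
        assert emb.explained_variance[3:].sum() / total < 1e-10

    def test_duplicated_cell_rows_identical(self, reference):
        m, _, _ = reference
        nm = normalize(filter_genes(m))
        genes = select_variable_genes(nm, 30)
        nm.values[:, 1] = nm.values[:, 0]
        emb = run_pca(nm, genes, max_pcs=5)
        assert np.allclose(emb.coords[0], emb.coords[1], atol=1e-10)

    def test_matches_dense_eigendecomposition(self):
        """Scores reproduce the covariance eigenstructure on a 20x10 instance."""
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 10))  # cells x genes
        nm = preprocess.NormalizedMatrix(
            values=X.T.copy(), size_factors=np.ones(20),
            gene_ids=[f"G{i}" for i in range(10)], barcodes=[f"C{j}" for j in range(20)],
        )
        emb = run_pca(nm, list(nm.gene_ids), max_pcs=10, scale=False)
        Xc = X - X.mean(axis=0)
        evals = np.sort(np.linalg.eigvalsh(np.cov(Xc.T)))[::-1]
        assert np.allclose(emb.explained_variance, evals[:len(emb.explained_variance)], atol=1e-8)
        # reconstructed covariance from scores+loadings matches the data covariance
        recon = emb.loadings @ np.diag(emb.explained_variance) @ emb.loadings.T
        assert np.allclose(recon, np.cov(Xc.T), atol=1e-8)

    def test_sign_convention_deterministic(self, reference):
        m, _, _ = reference
        nm = normalize(filter_genes(m))
        genes = select_variable_genes(nm, 30)
        a = run_pca(nm, genes, max_pcs=5)
        b = run_pca(nm, genes, max_pcs=5)
        assert np.array_equal(a.coords, b.coords)
        for j in range(a.loadings.shape[1]):
            assert a.loadings[np.argmax(np.abs(a.loadings[:, j])), j] > 0


class TestElbow:
    def test_worked_example(self):
        """Hand-applied rule on (10,5,1,0.01,0.009): first sub-threshold drop at k=3."""
        assert choose_elbow([10, 5, 1, 0.01, 0.009], drop_fraction=0.1, floor=1) == 3

    def test_flat_spectrum_returns_cap(self):
        assert choose_elbow(np.ones(20), drop_fraction=0.1, floor=1, cap=7) == 7

    def test_single_component(self):
        assert choose_elbow([5.0], floor=1) == 1

    def test_short_vector_returns_full_length_with_warning(self):
        with pytest.warns(UserWarning):
            assert choose_elbow([3.0, 1.0], floor=5) == 2

    def test_floor_applies(self):
        assert choose_elbow([10, 5, 1, 0.01, 0.009, 0.008], drop_fraction=0.1, floor=5) == 5


class TestClustering:
    @staticmethod
    def _blob_embedding(seed=0, sep=10.0, n=60):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, size=(n, 5))
        b = rng.normal(0, 1, size=(n, 5))
        b[:, 0] += sep
        coords = np.vstack([a, b])
        return Embedding(
            coords=coords, explained_variance=np.ones(5),
            loadings=np.eye(5), gene_ids=np.arange(5).astype(object),
            barcodes=np.array([f"C{i}" for i in range(2 * n)], dtype=object),
        ), np.array([0] * n + [1] * n)

    def test_two_blobs_recovered_exactly(self):
        emb, truth = self._blob_embedding()
        labels = cluster_cells(emb, k_neighbors=20, seed=1)["cluster"]
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_low_resolution_gives_single_cluster(self):
        emb, _ = self._blob_embedding(sep=3.0)
        labels = cluster_cells(emb, k_neighbors=15, resolution=1e-4, seed=1)["cluster"]
        assert labels.nunique() == 1

    def test_partition_beats_singletons(self):
        emb, _ = self._blob_embedding()
        labels = cluster_cells(emb, k_neighbors=15, seed=1)["cluster"].to_numpy()
        q = modularity(emb, labels, k_neighbors=15)
        q_singl = modularity(emb, np.arange(len(labels)), k_neighbors=15)
        assert q >= q_singl

    def test_seed_reproducibility(self):
        emb, _ = self._blob_embedding()
        a = cluster_cells(emb, k_neighbors=15, seed=3)["cluster"]
        b = cluster_cells(emb, k_neighbors=15, seed=3)["cluster"]
        assert a.equals(b)

    def test_k_too_large_rejected(self):
        emb, _ = self._blob_embedding(n=5)
        with pytest.raises(ValidationError):
            cluster_cells(emb, k_neighbors=50)
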