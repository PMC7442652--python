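"""QC filtering, normalization/residualization, and SNN/Louvain clustering."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import sparse
from sklearn.metrics import adjusted_rand_score

from conftest import make_adata
from sncelltype.atlas import (
    ClusterParams,
    EmptyAtlasError,
    QcThresholds,
    UNASSIGNED,
    cluster,
    normalize_and_regress,
    qc_filter,
)
from sncelltype.presets import default_cluster_params
from sncelltype.synth import AtlasSimSpec, simulate_atlas


class TestQcFilter:
    def test_low_detection_gene_removed(self):
        # gene 3 is nonzero in only 2 of 6 cells -> dropped at the
        # 3-cell detection threshold; all others kept
        counts = np.array(
            [
                [5, 3, 2, 1],
                [4, 2, 3, 2],
                [6, 1, 4, 0],
                [5, 2, 2, 0],
                [3, 4, 1, 0],
                [4, 3, 3, 0],
            ]
        )
        a = make_adata(counts)
        out, rep = qc_filter(
            a, QcThresholds(min_cells_per_gene=3, min_genes_per_cell=2,
                            max_umi=1000)
        )
        assert list(out.var_names) == ["g0", "g1", "g2"]
        assert rep.genes_removed_low_detection == 1
        assert rep.n_cells_out == 6

    def test_high_mito_cell_removed_regardless(self):
        counts = np.tile([0, 10, 10, 10], (5, 1))
        counts[0] = [40, 100, 100, 100]  # mito fraction 40/340 > 0.05
        a = make_adata(counts, mito=[True, False, False, False])
        out, rep = qc_filter(
            a, QcThresholds(min_cells_per_gene=1, min_genes_per_cell=1,
                            max_umi=10_000)
        )
        assert "cell0" not in out.obs_names
        assert rep.cells_removed_mito == 1

    def test_identity_when_all_pass(self):
        counts = np.full((6, 4), 5)
        a = make_adata(counts)
        out, rep = qc_filter(
            a, QcThresholds(min_cells_per_gene=1, min_genes_per_cell=1,
                            max_umi=100)
        )
        assert out.shape == a.shape
        assert rep.genes_removed_low_detection == 0
        assert rep.cells_removed_low_genes == rep.cells_removed_mito == 0

    def test_idempotent_with_resolved_caps(self):
        adata = simulate_atlas(
            AtlasSimSpec(n_cell_types=2, cells_per_type=[150, 150],
                         n_genes=400, mito_fraction_outlier_rate=0.05, seed=2)
        )
        thr = QcThresholds(min_genes_per_cell=150)
        once, rep1 = qc_filter(adata, thr)
        thr2 = QcThresholds(min_genes_per_cell=150,
                            max_umi=rep1.resolved_max_umi)
        twice, rep2 = qc_filter(once, thr2)
        assert twice.shape == once.shape
        assert rep2.n_cells_out == rep1.n_cells_out

    def test_empty_result_is_loud(self):
        a = make_adata(np.ones((4, 3)))
        with pytest.raises(EmptyAtlasError):
            qc_filter(a, QcThresholds(min_genes_per_cell=10, max_umi=100))


class TestNormalizeRegress:
    def test_residualization_matches_ols_oracle(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(5, size=(50, 20))
        a = make_adata(counts)
        a, _ = qc_filter(a, QcThresholds(min_cells_per_gene=1,
                                         min_genes_per_cell=1, max_umi=1e6))
        a = normalize_and_regress(a)
        Y = np.asarray(sparse.csr_matrix(a.layers["lognorm"]).todense())
        covs = ["n_umi", "mito_fraction", "ribo_fraction"]
        for j in [0, 7, 19]:
            X = sm.add_constant(np.column_stack(
                [a.obs[c].to_numpy(dtype=float) for c in covs if a.obs[c].std() > 0]
            ))
            resid = sm.OLS(Y[:, j], X).fit().resid
            resid = resid - resid.mean()
            sd = resid.std()
            expect = resid / (sd if sd > 0 else 1.0)
            np.testing.assert_allclose(a.layers["scaled"][:, j], expect,
                                       atol=1e-8)

    def test_covariate_driven_gene_flattened(self):
        rng = np.random.default_rng(1)
        n = 80
        counts = rng.poisson(20, size=(n, 30))
        mito_counts = rng.integers(0, 40, n)  # strong mito-fraction spread
        counts[:, 0] = mito_counts
        counts[:, 1] = mito_counts * 3  # driven by the same technical axis
        a = make_adata(counts, mito=[True] + [False] * 29)
        a, _ = qc_filter(a, QcThresholds(min_cells_per_gene=1,
                                         min_genes_per_cell=1, max_umi=1e6,
                                         max_mito=1.0))
        a = normalize_and_regress(a)
        lognorm = np.asarray(sparse.csr_matrix(a.layers["lognorm"]).todense())
        raw_var = lognorm[:, 1].var()
        # variance along the technical covariate is regressed away
        Y = np.asarray(a.layers["scaled"])
        r = np.corrcoef(Y[:, 1], a.obs["mito_fraction"])[0, 1]
        assert raw_var > 0
        assert abs(r) < 1e-8

    def test_identical_cells_get_identical_vectors(self):
        counts = np.vstack([np.arange(1, 11), np.arange(1, 11),
                            np.arange(10, 0, -1)])
        a = make_adata(counts)
        a, _ = qc_filter(a, QcThresholds(min_cells_per_gene=1,
                                         min_genes_per_cell=1, max_umi=1e6))
        a = normalize_and_regress(a)
        np.testing.assert_array_equal(a.layers["scaled"][0],
                                      a.layers["scaled"][1])

    def test_zero_depth_cell_rejected(self):
        counts = np.ones((4, 3))
        counts[2] = 0
        a = make_adata(counts)
        with pytest.raises(ValueError, match="zero-depth"):
            normalize_and_regress(a)


class TestCluster:
    def test_recovers_planted_types(self, small_atlas):
        a = cluster(small_atlas.copy(), default_cluster_params(), seed=0)
        mask = (a.obs["cluster"] != UNASSIGNED).to_numpy()
        ari = adjusted_rand_score(a.obs["true_type"][mask],
                                  a.obs["cluster"][mask])
        assert ari >= 0.9

    def test_small_cluster_dropped(self):
        spec = AtlasSimSpec(n_cell_types=3, cells_per_type=[120, 120, 25],
                            n_genes=400, marker_fold_change=8.0, seed=6)
        a = simulate_atlas(spec)
        a, _ = qc_filter(a, QcThresholds(min_genes_per_cell=120))
        a = normalize_and_regress(a)
        a = cluster(a, ClusterParams(n_hvg=400, n_pcs=10, snn_k=15,
                                     resolution=0.5, min_cluster_size=30),
                    seed=0)
        small_type = (a.obs["true_type"] == "type2").to_numpy()
        # the 25-cell type cannot form a >=30-cell cluster
        assert (a.obs["cluster"][small_type] == UNASSIGNED).mean() > 0.8
        sizes = a.obs["cluster"].value_counts()
        assert (sizes.drop(UNASSIGNED, errors="ignore") >= 30).all()

    def test_cell_order_invariance(self, small_atlas):
        params = default_cluster_params()
        a = cluster(small_atlas.copy(), params, seed=0)
        rng = np.random.default_rng(0)
        perm = rng.permutation(small_atlas.n_obs)
        b = cluster(small_atlas[perm].copy(), params, seed=0)
        ari = adjusted_rand_score(
            a.obs["cluster"][perm].to_numpy(), b.obs["cluster"].to_numpy()
        )
        assert ari == pytest.approx(1.0)

    def test_k_must_be_smaller_than_cells(self, small_atlas):
        with pytest.raises(ValueError):
            cluster(small_atlas.copy(),
                    ClusterParams(snn_k=small_atlas.n_obs), seed=0)

    def test_requires_normalization(self):
        a = make_adata(np.ones((10, 5)))
        with pytest.raises(ValueError, match="normalize"):
            cluster(a, ClusterParams(snn_k=3), seed=0)
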