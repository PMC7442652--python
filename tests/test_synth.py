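"""Generators: shape contracts, determinism, and null calibration."""

import igraph
import numpy as np
import pytest

from sncelltype.synth import (
    AtlasSimSpec,
    GwasSimSpec,
    PpiSimSpec,
    simulate_atlas,
    simulate_go,
    simulate_gwas,
    simulate_ppi,
)


class TestAtlasSim:
    def test_shapes_and_metadata(self):
        spec = AtlasSimSpec(n_cell_types=3, cells_per_type=[100, 100, 100],
                            n_genes=500, seed=0)
        a = simulate_atlas(spec)
        assert a.shape == (300, 500)
        assert set(a.obs["true_type"]) == {"type0", "type1", "type2"}
        for col in ["region", "glial", "sample"]:
            assert col in a.obs
        assert a.var["mito"].sum() == 10 and a.var["ribo"].sum() == 10
        assert (a.X.data >= 0).all()
        assert len(a.uns["true_markers"]["type0"]) == spec.markers_per_type

    def test_deterministic_under_seed(self):
        spec = AtlasSimSpec(n_cell_types=2, cells_per_type=[50, 50],
                            n_genes=200, seed=42)
        a, b = simulate_atlas(spec), simulate_atlas(spec)
        assert (a.X != b.X).nnz == 0
        assert a.obs.equals(b.obs)

    def test_marker_fold_raises_marker_means(self):
        spec = AtlasSimSpec(n_cell_types=2, cells_per_type=[200, 200],
                            n_genes=300, marker_fold_change=8.0, seed=1)
        a = simulate_atlas(spec)
        X = np.asarray(a.X.todense())
        m0 = [a.var_names.get_loc(g) for g in a.uns["true_markers"]["type0"]]
        in0 = (a.obs["true_type"] == "type0").to_numpy()
        ratio = X[in0][:, m0].mean() / X[~in0][:, m0].mean()
        assert 5.0 < ratio < 12.0

    @pytest.mark.parametrize(
        "kw",
        [
            dict(n_cell_types=2, cells_per_type=[10], n_genes=100),
            dict(n_cell_types=2, cells_per_type=[10, 10], n_genes=30,
                 markers_per_type=10),
            dict(n_cell_types=1, cells_per_type=[5], n_genes=100,
                 mito_fraction_outlier_rate=1.5),
            dict(n_cell_types=1, cells_per_type=[5], n_genes=100,
                 marker_fold_change=0.0),
        ],
    )
    def test_invalid_spec_rejected(self, kw):
        with pytest.raises(ValueError):
            AtlasSimSpec(**kw)


class TestGwasSim:
    def test_null_mean_chisq_is_one(self):
        spec = GwasSimSpec(n_blocks=250, snps_per_block=40, within_block_r=0.5,
                           n_samples=10_000, seed=0)
        sim = simulate_gwas(spec)
        chi2 = sim.study.z ** 2
        # 10,000 SNPs; mean chi2 SE is inflated by within-block LD
        se = np.sqrt(2.0 / len(chi2)) * 3
        assert abs(chi2.mean() - 1.0) < 3 * se + 0.05

    def test_fully_shared_pair_correlates_at_causal_snps(self):
        z1_all, z2_all = [], []
        for rep in range(50):
            spec = GwasSimSpec(
                n_blocks=20, snps_per_block=20, within_block_r=0.3,
                n_samples=100_000, genes_per_block=2,
                gene_sets={"c": [f"G{i:05d}" for i in range(10)]},
                causal_gene_sets=[("c", 1e-4)],
                trait2_causal_sets=[("c", 1e-4)],
                shared_fraction=1.0, seed=rep,
            )
            sim = simulate_gwas(spec)
            causal = sim.true_beta["trait1"].to_numpy() != 0
            z1_all.append(sim.studies[0].z[causal])
            z2_all.append(sim.studies[1].z[causal])
        r = np.corrcoef(np.concatenate(z1_all), np.concatenate(z2_all))[0, 1]
        assert r > 0.9

    def test_unlinked_block_empirical_correlation_identity(self):
        # many iid blocks of the same R stand in for repeated draws
        spec = GwasSimSpec(n_blocks=10_000, snps_per_block=8,
                           within_block_r=0.0, n_samples=1_000,
                           genes_per_block=2, seed=3)
        sim = simulate_gwas(spec)
        Z = sim.study.z.reshape(10_000, 8)
        C = np.corrcoef(Z.T)
        off = C[~np.eye(8, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_ld_block_empirical_correlation_matches_r(self):
        spec = GwasSimSpec(n_blocks=10_000, snps_per_block=6,
                           within_block_r=0.5, n_samples=1_000,
                           genes_per_block=2, seed=4)
        sim = simulate_gwas(spec)
        Z = sim.study.z.reshape(10_000, 6)
        C = np.corrcoef(Z.T)
        off = C[~np.eye(6, dtype=bool)]
        assert np.abs(off - 0.5).max() < 0.05

    def test_genome_shared_across_noise_seeds(self):
        base = dict(n_blocks=5, snps_per_block=20, within_block_r=0.2,
                    n_samples=1000, genome_seed=9)
        a = simulate_gwas(GwasSimSpec(**base, seed=1))
        b = simulate_gwas(GwasSimSpec(**base, seed=2))
        assert a.genes.df.equals(b.genes.df)
        assert not np.allclose(a.study.z, b.study.z)

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            GwasSimSpec(n_blocks=2, snps_per_block=10, within_block_r=1.0,
                        n_samples=100)
        with pytest.raises(ValueError):
            GwasSimSpec(n_blocks=2, snps_per_block=10, within_block_r=0.2,
                        n_samples=100, causal_gene_sets=[("x", -1.0)])
        with pytest.raises(ValueError):
            # causal set never declared in gene_sets
            simulate_gwas(GwasSimSpec(n_blocks=2, snps_per_block=10,
                                      within_block_r=0.2, n_samples=100,
                                      causal_gene_sets=[("x", 1e-4)]))


class TestPpiSim:
    def test_zero_between_gives_exact_components(self):
        g, labels = simulate_ppi(PpiSimSpec(n_modules=3, genes_per_module=30,
                                            p_within=0.5, p_between=0.0, seed=0))
        comps = g.connected_components()
        mods = {tuple(sorted(c)) for c in comps if len(c) > 1}
        planted = {
            tuple(sorted(np.flatnonzero(labels == k))) for k in range(3)
        }
        # every non-singleton component sits inside one planted module
        for c in comps:
            assert len({labels[i] for i in c}) == 1
        assert g.ecount() > 0

    def test_single_module(self):
        g, labels = simulate_ppi(PpiSimSpec(n_modules=1, genes_per_module=40,
                                            p_within=0.3, p_between=0.0, seed=1))
        assert set(labels) == {0}
        assert isinstance(g, igraph.Graph)
        assert not any(e.source == e.target for e in g.es)

    def test_reproducible_and_validated(self):
        spec = PpiSimSpec(n_modules=2, genes_per_module=20, p_within=0.4,
                          p_between=0.05, seed=7)
        g1, _ = simulate_ppi(spec)
        g2, _ = simulate_ppi(spec)
        assert sorted(g1.get_edgelist()) == sorted(g2.get_edgelist())
        with pytest.raises(ValueError):
            PpiSimSpec(n_modules=2, genes_per_module=10, p_within=0.1,
                       p_between=0.4)
        with pytest.raises(ValueError):
            PpiSimSpec(n_modules=2, genes_per_module=10, p_within=1.4,
                       p_between=0.1)


class TestGoSim:
    def test_sizes_and_seeding(self):
        universe = [f"g{i}" for i in range(200)]
        planted = universe[:40]
        terms = simulate_go(universe, 30, (5, 25), seed=0,
                            seeded_terms={"GO:PLANTED": planted})
        assert len(terms) == 31
        for name, genes in terms.items():
            if name == "GO:PLANTED":
                assert sorted(genes) == sorted(planted)
            else:
                assert 5 <= len(genes) <= 25
            assert set(genes) <= set(universe)

    def test_errors(self):
        with pytest.raises(ValueError):
            simulate_go([], 5, (1, 2))
        with pytest.raises(ValueError):
            simulate_go(["a", "b"], 5, (1, 10))
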