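"""Gene statistics and the competitive gene-set engine."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sncelltype.datatypes import GeneAnnotation
from sncelltype.geneassoc import (
    celltype_scan,
    competitive_set_test,
    compute_gene_stats,
    gene_statistic,
    map_snps_to_genes,
    module_scan,
)


def toy_sumstats(positions, chrom="1", z=None):
    n = len(positions)
    return pd.DataFrame(
        {"SNP": [f"rs{i}" for i in range(n)], "CHR": chrom, "BP": positions,
         "A1": "A", "A2": "G", "Z": z if z is not None else np.zeros(n),
         "N": 1000}
    )


class TestSnpToGene:
    def test_hand_enumeration_with_window(self):
        genes = GeneAnnotation(pd.DataFrame(
            {"gene": ["gA", "gB", "gC"], "CHR": "1",
             "start": [100_000, 200_000, 205_000],
             "end": [110_000, 204_000, 215_000]}
        ))
        pos = [95_000, 100_001, 109_999, 115_000, 199_000, 204_500,
               212_000, 230_000, 50_000, 120_001]
        # rs9 (pos0 = 120,000) sits exactly at end + window: excluded by
        # the half-open convention
        out = map_snps_to_genes(toy_sumstats(pos), genes, window_kb=10)
        assert out["gA"] == ["rs0", "rs1", "rs2", "rs3"]
        assert out["gB"] == ["rs4", "rs5", "rs6"]
        assert out["gC"] == ["rs4", "rs5", "rs6"]

    def test_boundary_snp_window_zero(self):
        genes = GeneAnnotation(pd.DataFrame(
            {"gene": ["g"], "CHR": "1", "start": [100], "end": [200]}
        ))
        # 1-based position 101 -> pos0 100 == start: inside
        # 1-based position 201 -> pos0 200 == end: outside (half-open)
        out = map_snps_to_genes(toy_sumstats([101, 201]), genes, window_kb=0)
        assert out["g"] == ["rs0"]

    def test_chromosome_dialects_normalized(self):
        genes = GeneAnnotation(pd.DataFrame(
            {"gene": ["g"], "CHR": "chr1", "start": [0], "end": [1000]}
        ))
        out = map_snps_to_genes(toy_sumstats([500], chrom="1"), genes,
                                window_kb=0)
        assert out["g"] == ["rs0"]


class TestGeneStatistic:
    def test_single_snp_identity(self):
        z = stats.norm.isf(0.025)  # two-sided p = 0.05
        stat, p = gene_statistic(np.array([z]), np.eye(1))
        assert p == pytest.approx(0.05, abs=1e-9)
        assert stat == pytest.approx(3.841, abs=5e-4)

    def test_perfect_ld_collapses_to_single_snp(self):
        z = 1.7
        _, p1 = gene_statistic(np.array([z]), np.eye(1))
        R = np.ones((2, 2))
        _, p2 = gene_statistic(np.array([z, z]), R)
        assert p2 == pytest.approx(p1, rel=1e-6)

    def test_independent_snps_exact_chi2(self):
        z = np.array([1.0, 2.0, 0.5])
        stat, p = gene_statistic(z, np.eye(3))
        assert p == pytest.approx(stats.chi2.sf(z @ z, 3), rel=1e-6)

    def test_matches_monte_carlo_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(3):
            m = 6
            W = rng.standard_normal((m, 3))
            S = W @ W.T + np.eye(m)
            d = np.sqrt(np.diag(S))
            R = S / np.outer(d, d)
            z = np.linalg.cholesky(R) @ rng.standard_normal(m)
            _, p = gene_statistic(z, R)
            lam = np.linalg.eigvalsh(R)
            draws = rng.chisquare(1, (200_000, m)) @ np.clip(lam, 0, None)
            p_mc = (draws >= z @ z).mean()
            if 0.02 < p_mc < 0.98:
                assert p == pytest.approx(p_mc, rel=0.05)

    def test_order_and_sign_invariance(self):
        rng = np.random.default_rng(5)
        W = rng.standard_normal((5, 3))
        S = W @ W.T + np.eye(5)
        d = np.sqrt(np.diag(S))
        R = S / np.outer(d, d)
        z = rng.standard_normal(5)
        _, p = gene_statistic(z, R)
        perm = [3, 1, 4, 0, 2]
        _, p_perm = gene_statistic(z[perm], R[np.ix_(perm, perm)])
        _, p_flip = gene_statistic(-z, R)
        assert p_perm == pytest.approx(p, rel=1e-9)
        assert p_flip == pytest.approx(p, rel=1e-12)

    def test_empty_gene_rejected(self):
        with pytest.raises(ValueError):
            gene_statistic(np.array([]), np.empty((0, 0)))

    def test_gene_p_uniform_under_null(self, null_gene_stats):
        # spec-level calibration: gene p-values from a null genome
        p = null_gene_stats.df["p"].to_numpy()
        assert len(p) == 1000
        assert stats.kstest(p, "uniform").pvalue > 0.01


def _toy_gene_stats(z_values, rng=None):
    n = len(z_values)
    rng = rng or np.random.default_rng(0)
    return pd.DataFrame(
        {"gene": [f"G{i}" for i in range(n)],
         "n_snps": rng.integers(2, 30, n),
         "length": rng.integers(5_000, 200_000, n),
         "stat": np.ones(n), "p": np.full(n, 0.5), "Z": z_values}
    )


class TestCompetitiveTest:
    def test_reduces_to_two_sample_t(self):
        from sncelltype.geneassoc import GeneStats

        rng = np.random.default_rng(1)
        z = rng.standard_normal(60)
        gs = GeneStats(_toy_gene_stats(z, rng))
        members = [f"G{i}" for i in range(15)]
        rec = competitive_set_test(gs, members, covariates=False)
        t_ref = stats.ttest_ind(z[:15], z[15:], equal_var=True,
                                alternative="greater")
        assert rec.stat == pytest.approx(t_ref.statistic, abs=1e-10)
        assert rec.p == pytest.approx(t_ref.pvalue, abs=1e-10)

    def test_hand_computed_t(self):
        from sncelltype.geneassoc import GeneStats

        jit = 1e-3 * np.array([1, -1, 2, -2])
        z = np.concatenate([2.0 + jit, np.zeros(8)])
        gs = GeneStats(_toy_gene_stats(z))
        rec = competitive_set_test(gs, [f"G{i}" for i in range(4)],
                                   covariates=False)
        x, y = z[:4], z[4:]
        sp = np.sqrt(((3 * x.var(ddof=1) + 7 * y.var(ddof=1)) / 10))
        t_hand = (x.mean() - y.mean()) / (sp * np.sqrt(1 / 4 + 1 / 8))
        assert rec.stat == pytest.approx(t_hand, rel=1e-10)

    def test_monotone_in_set_signal(self):
        from sncelltype.geneassoc import GeneStats

        rng = np.random.default_rng(2)
        z = rng.standard_normal(100)
        members = [f"G{i}" for i in range(20)]
        betas = []
        for delta in [0.0, 0.5, 1.0]:
            z2 = z.copy()
            z2[:20] += delta
            rec = competitive_set_test(GeneStats(_toy_gene_stats(z2, rng)),
                                       members)
            betas.append(rec.beta)
        assert betas[0] < betas[1] < betas[2]

    def test_conditioning_on_itself_rejected(self, null_gene_stats):
        genes = list(null_gene_stats.df["gene"][:30])
        with pytest.raises(ValueError, match="identical"):
            competitive_set_test(null_gene_stats, genes,
                                 condition_sets={"same": genes})

    def test_tiny_set_rejected(self, null_gene_stats):
        with pytest.raises(ValueError, match=">= 2 genes"):
            competitive_set_test(null_gene_stats,
                                 [null_gene_stats.df["gene"].iloc[0]])


class TestScans:
    def test_single_cell_type_q_equals_p(self, null_gene_stats):
        genes = list(null_gene_stats.df["gene"][:40])
        out = celltype_scan(null_gene_stats, {"only": genes})
        assert out["q"].iloc[0] == pytest.approx(out["p"].iloc[0])

    def test_bonferroni_over_cell_types(self, null_gene_stats):
        genes = null_gene_stats.df["gene"].to_numpy()
        sets = {f"ct{i}": list(genes[i * 40:(i + 1) * 40]) for i in range(5)}
        out = celltype_scan(null_gene_stats, sets)
        np.testing.assert_allclose(out["q"], np.minimum(1, out["p"] * 5))

    def test_duplicate_module_doubles_family(self, null_gene_stats):
        genes = list(null_gene_stats.df["gene"][:50])
        out = module_scan(null_gene_stats, {"m1": genes, "m2": genes})
        assert out["p"].iloc[0] == pytest.approx(out["p"].iloc[1])
        np.testing.assert_allclose(out["q"], np.minimum(1, out["p"] * 2))

    def test_uncovered_module_skipped_with_warning(self, null_gene_stats):
        genes = list(null_gene_stats.df["gene"][:40])
        with pytest.warns(UserWarning, match="disjoint"):
            out = module_scan(null_gene_stats,
                              {"ok": genes, "ghost": ["nope1", "nope2"]})
        assert list(out["set"]) == ["ok"]


class TestComputeGeneStats:
    def test_planted_set_genes_score_high(self):
        from sncelltype.presets import MID_EFFECT_VAR, gwas_spec_for_genes
        from sncelltype.synth import simulate_gwas

        universe = [f"G{i:05d}" for i in range(240)]
        causal = universe[:24]
        sim = simulate_gwas(gwas_spec_for_genes(
            universe, gene_sets={"c": causal},
            causal_gene_sets=[("c", MID_EFFECT_VAR)], seed=8,
        ))
        gs = compute_gene_stats(sim.study, sim.panel, sim.genes)
        df = gs.df.set_index("gene")
        z_causal = df.loc[[g for g in causal if g in df.index], "Z"].mean()
        z_null = df.loc[[g for g in universe[24:] if g in df.index], "Z"].mean()
        assert z_causal > z_null + 1.0
        rec = competitive_set_test(gs, causal)
        assert rec.p < 1e-4
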