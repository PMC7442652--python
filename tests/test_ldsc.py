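"""Stratified LD-score regression: annotations, scores, fits, conditioning."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sncelltype.datatypes import GeneAnnotation, GwasStudy, LDBlock, LDPanel
from sncelltype.ldsc import (
    Annotation,
    build_annotation,
    conditional_fit,
    fit_stratified,
    ld_scores,
)
from sncelltype.presets import gwas_spec_for_genes
from sncelltype.scenarios import conditional_distinct_sets, ldsc_noiseless_recovery
from sncelltype.synth import simulate_gwas


def _sumstats(snps, positions, z=None, n=1000):
    return GwasStudy(pd.DataFrame(
        {"SNP": snps, "CHR": "1", "BP": positions, "A1": "A", "A2": "G",
         "Z": z if z is not None else np.zeros(len(snps)), "N": n}
    ))


class TestBuildAnnotation:
    def test_hand_enumeration(self):
        genes = GeneAnnotation(pd.DataFrame(
            {"gene": ["g1", "g2"], "CHR": "1",
             "start": [10_000, 50_000], "end": [20_000, 60_000]}
        ))
        pos = list(range(1, 70_002, 5_000))  # 15 SNPs every 5 kb
        ss = _sumstats([f"s{i}" for i in range(len(pos))], pos)
        annot = build_annotation({"set": ["g1"]}, genes, ss, window_kb=5)
        member = annot.df["set"]
        # window [5,000, 25,000): SNPs at 1-based 5,001..25,001 -> pos0 in range
        expect = {f"s{i}" for i, p in enumerate(pos) if 5_000 <= p - 1 < 25_000}
        assert set(member[member == 1].index) == expect

    def test_baseline_all_ones_and_subset(self):
        genes = GeneAnnotation(pd.DataFrame(
            {"gene": ["g"], "CHR": "1", "start": [0], "end": [100_000]}
        ))
        ss = _sumstats(["a", "b"], [50, 99_999])
        annot = build_annotation({"everything": ["g"]}, genes, ss, window_kb=0)
        assert (annot.df["baseline"] == 1).all()
        assert (annot.df["everything"] == annot.df["baseline"]).all()

    def test_empty_category_dropped(self):
        genes = GeneAnnotation(pd.DataFrame(
            {"gene": ["g"], "CHR": "2", "start": [0], "end": [100]}
        ))
        ss = _sumstats(["a"], [500_000])
        annot = build_annotation({"far": ["g"]}, genes, ss, window_kb=0)
        assert "far" not in annot.df.columns


class TestLdScores:
    def test_identity_blocks_give_unit_baseline(self):
        panel = LDPanel([LDBlock(np.array(["a", "b"]), np.eye(2))])
        annot = Annotation(pd.DataFrame({"baseline": [1, 1]}, index=["a", "b"]))
        sc = ld_scores(annot, panel)
        np.testing.assert_allclose(sc["baseline"], 1.0)

    def test_three_snp_block_summation(self):
        r = np.sqrt(0.5)
        R = np.full((3, 3), r)
        np.fill_diagonal(R, 1.0)
        panel = LDPanel([LDBlock(np.array(["a", "b", "c"]), R)])
        annot = Annotation(pd.DataFrame({"baseline": [1, 1, 1]},
                                        index=["a", "b", "c"]))
        sc = ld_scores(annot, panel)
        np.testing.assert_allclose(sc["baseline"], 2.0)  # 1 + 0.5 + 0.5

    def test_category_equal_baseline_gives_identical_columns(self):
        R = np.eye(3)
        panel = LDPanel([LDBlock(np.array(["a", "b", "c"]), R)])
        annot = Annotation(pd.DataFrame({"cat": [1, 1, 1]},
                                        index=["a", "b", "c"]))
        sc = ld_scores(annot, panel)
        assert (sc["cat"] == sc["baseline"]).all()


class TestFitStratified:
    def test_noiseless_recovery_to_machine_precision(self):
        assert ldsc_noiseless_recovery(tau=5e-4) < 1e-12

    def test_zero_category_leaves_others_unchanged(self):
        rng = np.random.default_rng(0)
        ell = rng.uniform(1, 6, 1500)
        base = ell + rng.uniform(0.1, 1.0, 1500)
        snps = [f"s{i}" for i in range(1500)]
        chi2 = 1000 * 3e-4 * ell + 1.0 + rng.normal(0, 0.05, 1500)
        study = _sumstats(snps, np.arange(1500) + 1, z=np.sqrt(chi2))
        s1 = pd.DataFrame({"baseline": base, "t": ell}, index=snps)
        s2 = s1.copy()
        s2["zero"] = 0.0
        f1 = fit_stratified(study, s1)
        f2 = fit_stratified(study, s2)
        assert abs(f1.tau["t"] - f2.tau["t"]) < 1e-10

    def test_duplicate_categories_rejected(self):
        snps = [f"s{i}" for i in range(200)]
        ell = np.linspace(1, 5, 200)
        study = _sumstats(snps, np.arange(200) + 1, z=np.ones(200))
        scores = pd.DataFrame({"baseline": ell, "a": ell}, index=snps)
        with pytest.raises(ValueError, match="duplicate"):
            fit_stratified(study, scores)

    def test_null_coefficient_p_uniform(self):
        # planted-null simulations: the one-sided coefficient p for a
        # random gene-set category should be uniform
        pvals = []
        universe = [f"G{i:05d}" for i in range(300)]
        for k in range(300):
            rng = np.random.default_rng(k)
            gset = sorted(rng.choice(universe, 40, replace=False))
            sim = simulate_gwas(gwas_spec_for_genes(
                universe, gene_sets={"s": gset}, causal_gene_sets=[],
                snps_per_block=40, seed=k,
            ))
            annot = build_annotation({"s": gset}, sim.genes, sim.study,
                                     window_kb=0.0)
            scores = ld_scores(annot, sim.panel)
            pvals.append(float(fit_stratified(sim.study, scores).p["s"]))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestConditionalFit:
    def test_disjoint_planted_sets_stay_distinct(self):
        res = conditional_distinct_sets(seed=5)
        assert res["p_A_given_B"] < 0.05
        assert res["p_B_given_A"] < 0.05

    def test_target_equal_control_rejected(self, ldsc_fixture=None):
        universe = [f"G{i:05d}" for i in range(100)]
        sim = simulate_gwas(gwas_spec_for_genes(
            universe, gene_sets={"s": universe[:20]}, snps_per_block=40, seed=0,
        ))
        annot = build_annotation({"s": universe[:20]}, sim.genes, sim.study)
        with pytest.raises(ValueError, match="control"):
            conditional_fit(sim.study, "s", annot, sim.panel, ["s"])

    def test_identical_set_relabeled_flagged(self):
        universe = [f"G{i:05d}" for i in range(100)]
        s1 = universe[:20]
        s2 = list(s1)  # same set under a different name
        sim = simulate_gwas(gwas_spec_for_genes(
            universe, gene_sets={"a": s1, "b": s2}, snps_per_block=40, seed=1,
        ))
        annot = build_annotation({"a": s1, "b": s2}, sim.genes, sim.study,
                                 window_kb=0.0)
        with pytest.raises(ValueError, match="duplicates"):
            conditional_fit(sim.study, "a", annot, sim.panel, ["b"])

    def test_disjoint_null_control_preserves_marginal(self):
        # control with no causal overlap and no SNP overlap: conditional
        # p close to the marginal p
        universe = [f"G{i:05d}" for i in range(600)]
        rng = np.random.default_rng(3)
        causal = sorted(rng.choice(universe[:300], 40, replace=False))
        null_ctl = sorted(rng.choice(universe[300:], 40, replace=False))
        sim = simulate_gwas(gwas_spec_for_genes(
            universe, gene_sets={"c": causal, "n": null_ctl},
            causal_gene_sets=[("c", 4.2e-5)], seed=3,
        ))
        annot = build_annotation({"c": causal, "n": null_ctl}, sim.genes,
                                 sim.study, window_kb=0.0)
        scores = ld_scores(annot, sim.panel)
        marg = fit_stratified(sim.study, scores[["baseline", "c"]])
        cond = conditional_fit(sim.study, "c", annot, sim.panel, ["n"],
                               scores=scores)
        d = abs(np.log10(max(cond.p["c"], 1e-300))
                - np.log10(max(marg.p["c"], 1e-300)))
        assert d < 0.3
        assert cond.verdict == "distinct"
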