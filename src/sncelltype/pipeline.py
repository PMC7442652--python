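"""End-to-end driver chaining all stages on the default synthetic study.

Stages: simulate -> process (QC, clustering, markers, specificity per
region) -> homogenize -> assoc (GWAS simulation, MAGMA-style and
LDSC-style cell-type scans, within-trait conditional decomposition,
cross-disorder matrix) -> modules (PPI communities, module-level risk
enrichment and conditioning, GO over-representation).

Every stage writes its result tables into the output directory and its
intermediate products into ``<out>/cache``; a completed stage (all files
present) is skipped on re-runs unless forced. All randomness flows from
the single config seed, so a re-run with the same config reproduces every
output byte for byte; the manifest records a hash per result file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .atlas import ClusterParams, QcThresholds, cluster, normalize_and_regress, qc_filter
from .geneassoc import celltype_scan, compute_gene_stats, GeneStats, module_scan
from .ldsc import build_annotation, conditional_fit, fit_stratified, ld_scores
from .markers import find_all_markers, homogenize_regions, specificity
from .netmod import detect_modules, go_overrepresentation, induce_celltype_network
from .presets import (
    MID_EFFECT_VAR,
    gwas_spec_for_genes,
    joint_atlas_spec,
    synthetic_qc_thresholds,
)
from .synth import PpiSimSpec, simulate_atlas, simulate_go, simulate_gwas, simulate_ppi
from .xtrait import condition_sumstats, cross_disorder_matrix, estimate_bxy

log = logging.getLogger(__name__)

STAGES = ["simulate", "process", "homogenize", "assoc", "modules"]


@dataclass
class RunConfig:
    """All pipeline parameters; round-trips through YAML unchanged."""

    out_dir: str = "results"
    seed: int = 0
    min_genes_per_cell: int = 300
    max_mito: float = 0.05
    max_ribo: float = 0.05
    n_hvg: int = 1200
    n_pcs: int = 15
    snn_k: int = 20
    resolution: float = 0.4
    min_cluster_size: int = 30
    specificity_decile: float = 0.10
    window_kb_magma: float = 10.0
    window_kb_ldsc: float = 100.0
    effect_var: float = MID_EFFECT_VAR
    min_module_size: int = 30
    log_level: str = "INFO"

    def qc_thresholds(self) -> QcThresholds:
        thr = synthetic_qc_thresholds()
        thr.min_genes_per_cell = self.min_genes_per_cell
        thr.max_mito = self.max_mito
        thr.max_ribo = self.max_ribo
        return thr

    def cluster_params(self) -> ClusterParams:
        return ClusterParams(
            n_hvg=self.n_hvg, n_pcs=self.n_pcs, snn_k=self.snn_k,
            resolution=self.resolution, min_cluster_size=self.min_cluster_size,
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    sio.write_results(df, path)


def _stage_simulate(cfg: RunConfig, out: Path, cache: Path) -> None:
    adata = simulate_atlas(joint_atlas_spec(seed=cfg.seed))
    adata.write_h5ad(cache / "atlas.h5ad")


def _annotate_clusters(adata: ad.AnnData, region: str) -> dict[str, str]:
    """Name clusters by their dominant planted type; fall back to cX."""
    names: dict[str, str] = {}
    used: set[str] = set()
    for c in adata.obs["cluster"].cat.categories:
        if c == "unassigned":
            continue
        sub = adata.obs.loc[adata.obs["cluster"] == c, "true_type"]
        dom = sub.value_counts().idxmax()
        name = f"{region}_{dom}"
        if name in used:
            name = f"{region}_{dom}_{c}"
        used.add(name)
        names[c] = name
    return names


def _stage_process(cfg: RunConfig, out: Path, cache: Path) -> None:
    adata = ad.read_h5ad(cache / "atlas.h5ad")
    for region in ["SN", "CTX"]:
        sub = adata[adata.obs["region"] == region].copy()
        sub, report = qc_filter(sub, cfg.qc_thresholds())
        sub = normalize_and_regress(sub)
        sub = cluster(sub, cfg.cluster_params(), seed=cfg.seed)
        names = _annotate_clusters(sub, region)
        sub.obs["cell_type"] = (
            sub.obs["cluster"].astype(str).map(names).fillna("unassigned")
        )
        # glial flag per cluster: majority vote over member cells
        glial = {
            names[c]: bool(
                sub.obs.loc[sub.obs["cluster"] == c, "glial"].mean() > 0.5
            )
            for c in names
        }
        sub.uns["cluster_glial"] = glial
        sub.write_h5ad(cache / f"atlas_{region}.h5ad")

        _write_tsv(report.to_frame(), out / f"qc_report_{region}.tsv")
        _write_tsv(
            pd.DataFrame(
                {
                    "barcode": sub.obs_names,
                    "cluster": sub.obs["cluster"].astype(str),
                    "cell_type": sub.obs["cell_type"],
                }
            ),
            out / f"clusters_{region}.tsv",
        )
        mk = find_all_markers(sub, cluster_key="cell_type")
        mk = mk[mk["cluster"] != "unassigned"]
        _write_tsv(mk, out / f"markers_{region}.tsv")
        spt = specificity(sub, cluster_key="cell_type", decile=cfg.specificity_decile)
        spt.scores.rename_axis("gene").reset_index().to_csv(
            out / f"specificity_{region}.tsv", sep="\t", index=False,
            float_format=sio.FLOAT_FORMAT,
        )
        sio.write_gmt(spt.gene_sets, out / f"genesets_{region}.gmt")


def _stage_homogenize(cfg: RunConfig, out: Path, cache: Path) -> None:
    sn = ad.read_h5ad(cache / "atlas_SN.h5ad")
    ctx = ad.read_h5ad(cache / "atlas_CTX.h5ad")
    sn_h, ctx_h = homogenize_regions(sn, ctx, seed=cfg.seed + 5)
    rows = []
    for tag, a in [("SN", sn), ("CTX", ctx), ("SN_homog", sn_h), ("CTX_homog", ctx_h)]:
        g = float(np.asarray(a.obs["glial"], dtype=bool).mean())
        rows.append((tag, a.n_obs, g))
    _write_tsv(
        pd.DataFrame(rows, columns=["atlas", "n_cells", "glial_fraction"]),
        out / "homogenize_report.tsv",
    )
    for region, a in [("SN", sn_h), ("CTX", ctx_h)]:
        spt = specificity(a, cluster_key="cell_type", decile=cfg.specificity_decile)
        sio.write_gmt(spt.gene_sets, out / f"genesets_{region}_homog.gmt")
        a.write_h5ad(cache / f"atlas_{region}_homog.h5ad")


def _trait_suite(cfg: RunConfig, universe: list[str], markers: dict[str, list[str]]):
    """Three traits with planted sets: one trait with two distinct causal
    cell types (DaN + ODC), and a pair sharing OPC loci while acting on
    GABA neurons through disjoint gene halves."""
    v = cfg.effect_var
    gaba = sorted(markers["GABA"])
    sets = {
        "DaN_true": sorted(markers["DaN"]),
        "ODC_true": sorted(markers["ODC"]),
        "OPC_true": sorted(markers["OPC"]),
        "GABA_h1": gaba[: len(gaba) // 2],
        "GABA_h2": gaba[len(gaba) // 2 :],
    }
    sim1 = simulate_gwas(
        gwas_spec_for_genes(
            universe,
            gene_sets=sets,
            causal_gene_sets=[("DaN_true", v), ("ODC_true", v)],
            trait_names=("PD_like", "_unused"),
            genome_seed=cfg.seed,
            seed=cfg.seed + 1,
        )
    )
    sim2 = simulate_gwas(
        gwas_spec_for_genes(
            universe,
            gene_sets=sets,
            causal_gene_sets=[("OPC_true", v), ("GABA_h1", v)],
            trait2_causal_sets=[("OPC_true", v), ("GABA_h2", v)],
            shared_fraction=1.0,
            trait_names=("SCZ_like", "BP_like"),
            genome_seed=cfg.seed,
            seed=cfg.seed + 2,
        )
    )
    studies = {s.trait: s for s in sim1.studies + sim2.studies}
    return studies, sim1.panel, sim1.genes


def _stage_assoc(cfg: RunConfig, out: Path, cache: Path) -> None:
    sn = ad.read_h5ad(cache / "atlas_SN.h5ad")
    universe = list(sn.var_names)
    markers = {k: list(v) for k, v in sn.uns["true_markers"].items()}
    studies, panel, genes = _trait_suite(cfg, universe, markers)
    for t, s in studies.items():
        sio.write_sumstats(s, cache / f"sumstats_{t}.tsv")

    region_sets = {
        region: sio.read_gmt(out / f"genesets_{region}.gmt")
        for region in ["SN", "CTX"]
    }
    homog_sets = {
        region: sio.read_gmt(out / f"genesets_{region}_homog.gmt")
        for region in ["SN", "CTX"]
    }

    # MAGMA-style scans, original and homogenized atlases
    gstats = {
        t: compute_gene_stats(s, panel, genes, window_kb=cfg.window_kb_magma)
        for t, s in studies.items()
    }
    for t, gs in gstats.items():
        gs.df.to_csv(cache / f"genestats_{t}.tsv", sep="\t", index=False,
                     float_format="%.10g")
    magma_rows, magma_h_rows = [], []
    for region in ["SN", "CTX"]:
        for t in sorted(studies):
            r = celltype_scan(gstats[t], region_sets[region], trait=t)
            r.insert(0, "region", region)
            magma_rows.append(r)
            rh = celltype_scan(gstats[t], homog_sets[region], trait=t)
            rh.insert(0, "region", region)
            magma_h_rows.append(rh)
    magma = pd.concat(magma_rows, ignore_index=True)
    magma_h = pd.concat(magma_h_rows, ignore_index=True)
    _write_tsv(magma, out / "celltype_assoc_magma.tsv")
    _write_tsv(magma_h, out / "celltype_assoc_magma_homog.tsv")

    # pre/post homogenization agreement of association profiles
    key = ["region", "trait", "set"]
    prof = magma[key + ["p"]].merge(magma_h[key + ["p"]], on=key,
                                    suffixes=("_orig", "_homog"))
    r = float(np.corrcoef(-np.log10(prof["p_orig"]), -np.log10(prof["p_homog"]))[0, 1])
    _write_tsv(
        pd.DataFrame({"comparison": ["magma_profiles"], "pearson_r": [r]}),
        out / "homog_profile_correlation.tsv",
    )

    # LDSC-style scan (SN and CTX categories in one annotation)
    all_sets = {**region_sets["SN"], **region_sets["CTX"]}
    annot = build_annotation(all_sets, genes, studies["PD_like"],
                             window_kb=cfg.window_kb_ldsc)
    scores = ld_scores(annot, panel)
    ldsc_rows = []
    for t in sorted(studies):
        for ct in sorted(all_sets):
            if ct not in annot.df.columns:
                continue
            fit = fit_stratified(studies[t], scores[["baseline", ct]])
            ldsc_rows.append(
                (t, ct, float(fit.tau[ct]), float(fit.se[ct]), float(fit.p[ct]))
            )
    ldsc = pd.DataFrame(ldsc_rows, columns=["trait", "set", "tau", "se", "p"])
    ldsc["q"] = np.minimum(1.0, ldsc["p"] * ldsc.groupby("trait")["p"].transform("size"))
    _write_tsv(ldsc, out / "celltype_assoc_ldsc.tsv")

    # within-trait conditional decomposition (distinct cell aetiologies?)
    cond_rows = []
    for target, control in [("SN_DaN", "SN_ODC"), ("SN_ODC", "SN_DaN")]:
        if target in annot.df.columns and control in annot.df.columns:
            fit = conditional_fit(studies["PD_like"], target, annot, panel,
                                  [control], scores=scores)
            cond_rows.append(
                ("PD_like", target, control, float(fit.tau[target]),
                 float(fit.p[target]), fit.verdict)
            )
    _write_tsv(
        pd.DataFrame(cond_rows, columns=["trait", "target", "control", "tau",
                                         "p", "verdict"]),
        out / "conditional_celltypes.tsv",
    )

    # cross-disorder conditioning matrix over SN cell types
    sn_annot = build_annotation(region_sets["SN"], genes, studies["PD_like"],
                                window_kb=cfg.window_kb_ldsc)
    sn_scores = ld_scores(sn_annot, panel)
    # eligibility from the competitive scan (the broader of the two
    # marginal engines); conditional p itself comes from stratified LDSC
    pair = {t: studies[t] for t in ["SCZ_like", "BP_like"]}
    marginal = magma[
        (magma["region"] == "SN") & magma["trait"].isin(pair)
    ][["trait", "set", "p"]]
    matrix = cross_disorder_matrix(pair, marginal, sn_annot, panel,
                                   scores=sn_scores)
    _write_tsv(matrix, out / "cross_disorder_matrix.tsv")

    # adjusted sumstats + gene stats for the module-level conditioning
    for t1, t2 in [("SCZ_like", "BP_like"), ("BP_like", "SCZ_like")]:
        pr = estimate_bxy(studies[t1], studies[t2], panel)
        adj = condition_sumstats(pr)
        sio.write_sumstats(adj, cache / f"sumstats_{t1}_adj_{t2}.tsv")
        gs = compute_gene_stats(adj, panel, genes, window_kb=cfg.window_kb_magma)
        gs.df.to_csv(cache / f"genestats_{t1}_adj_{t2}.tsv", sep="\t",
                     index=False, float_format="%.10g")


def _load_genestats(path: Path) -> GeneStats:
    return GeneStats(pd.read_csv(path, sep="\t"))


def _stage_modules(cfg: RunConfig, out: Path, cache: Path) -> None:
    """Cell-type PPI networks for DaN, GABA and OPC; module-level risk
    scans, cross-disorder module conditioning, and GO enrichment.

    Each cell type's network carries planted communities, the first of
    which is seeded with that type's causal marker genes, so risk should
    refine to one module per associated cell type."""
    sn = ad.read_h5ad(cache / "atlas_SN.h5ad")
    markers = {k: list(v) for k, v in sn.uns["true_markers"].items()}
    sets = sio.read_gmt(out / "genesets_SN.gmt")

    all_modules: dict[str, list[str]] = {}
    universes: dict[str, list[str]] = {}
    seeded: dict[str, list[str]] = {}
    for i, (ct, true_type) in enumerate(
        [("SN_DaN", "DaN"), ("SN_GABA", "GABA"), ("SN_OPC", "OPC")]
    ):
        ct_set = sets.get(ct)
        if ct_set is None:
            log.warning("no %s gene set recovered; using planted markers", ct)
            ct_set = markers[true_type]
        # planted communities of equal size; causal markers lead the list
        # so they land together in the first community
        lead = [g for g in markers[true_type] if g in ct_set]
        others = sorted(g for g in ct_set if g not in lead)
        per_mod = 40
        n_mod = max(1, len(ct_set) // per_mod)
        ordered = (lead + others)[: n_mod * per_mod]
        g, _ = simulate_ppi(
            PpiSimSpec(
                n_modules=n_mod,
                genes_per_module=per_mod,
                p_within=0.3,
                p_between=0.01,
                gene_ids=ordered,
                seed=cfg.seed + 3 + i,
            )
        )
        net = induce_celltype_network(g, ct_set, set_name=ct)
        mset = detect_modules(net, seed=cfg.seed + 3 + i, cell_type=ct,
                              min_module_size=cfg.min_module_size)
        all_modules.update(mset.modules)
        universes[ct] = list(net.vs["name"])
        first = f"{ct}_M1"
        if first in mset.modules:
            seeded[f"GO:SEEDED_{ct}"] = mset.modules[first]
    sio.write_gmt(all_modules, out / "modules_SN.gmt")

    gstats = {
        t: _load_genestats(cache / f"genestats_{t}.tsv")
        for t in ["PD_like", "SCZ_like", "BP_like"]
    }
    scans = [module_scan(gs, all_modules, trait=t) for t, gs in sorted(gstats.items())]
    _write_tsv(pd.concat(scans, ignore_index=True), out / "module_assoc.tsv")

    cond = []
    for t1, t2 in [("SCZ_like", "BP_like"), ("BP_like", "SCZ_like")]:
        gs = _load_genestats(cache / f"genestats_{t1}_adj_{t2}.tsv")
        cond.append(module_scan(gs, all_modules, trait=f"{t1}|{t2}"))
    _write_tsv(pd.concat(cond, ignore_index=True), out / "module_assoc_conditional.tsv")

    enr = []
    for ct, universe in universes.items():
        terms = simulate_go(
            universe=sorted(universe),
            n_terms=50,
            term_size_range=(10, 40),
            seed=cfg.seed + 4,
            seeded_terms={k: v for k, v in seeded.items() if k.endswith(ct)},
        )
        for mid, genes_ in all_modules.items():
            if not mid.startswith(ct):
                continue
            e = go_overrepresentation(genes_, terms, universe=universe)
            e.insert(0, "module", mid)
            enr.append(e.head(20))
    _write_tsv(
        pd.concat(enr, ignore_index=True) if enr else
        pd.DataFrame(columns=["module", "term", "term_size", "overlap", "p"]),
        out / "go_enrichment.tsv",
    )


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "process": _stage_process,
    "homogenize": _stage_homogenize,
    "assoc": _stage_assoc,
    "modules": _stage_modules,
}

_STAGE_OUTPUTS = {
    "simulate": ["cache/atlas.h5ad"],
    "process": [
        "qc_report_SN.tsv", "qc_report_CTX.tsv", "clusters_SN.tsv",
        "clusters_CTX.tsv", "markers_SN.tsv", "markers_CTX.tsv",
        "specificity_SN.tsv", "specificity_CTX.tsv", "genesets_SN.gmt",
        "genesets_CTX.gmt", "cache/atlas_SN.h5ad", "cache/atlas_CTX.h5ad",
    ],
    "homogenize": [
        "homogenize_report.tsv", "genesets_SN_homog.gmt", "genesets_CTX_homog.gmt",
    ],
    "assoc": [
        "celltype_assoc_magma.tsv", "celltype_assoc_magma_homog.tsv",
        "homog_profile_correlation.tsv", "celltype_assoc_ldsc.tsv",
        "conditional_celltypes.tsv", "cross_disorder_matrix.tsv",
        "cache/genestats_PD_like.tsv",
        "cache/genestats_SCZ_like_adj_BP_like.tsv",
        "cache/genestats_BP_like_adj_SCZ_like.tsv",
    ],
    "modules": [
        "modules_SN.gmt", "module_assoc.tsv",
        "module_assoc_conditional.tsv", "go_enrichment.tsv",
    ],
}

RESULT_FILES = sorted(
    f for files in _STAGE_OUTPUTS.values() for f in files
    if not f.startswith("cache/")
)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, force: bool | str = False) -> Path:
    """Execute all stages; returns the output directory.

    ``force=True`` recomputes everything; ``force="<stage>"`` recomputes
    that stage and all downstream stages. A stage whose outputs all exist
    is otherwise skipped. Fails loudly on stage errors, leaving earlier
    results in place.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out = Path(config.out_dir)
    cache = out / "cache"
    cache.mkdir(parents=True, exist_ok=True)
    cfg_path = out / "config.yaml"
    if cfg_path.exists() and RunConfig.from_yaml(cfg_path) != config:
        log.info("configuration changed; recomputing all stages")
        force = True
    config.to_yaml(cfg_path)

    forced = False
    for stage in STAGES:
        if force is True or (isinstance(force, str) and force == stage):
            forced = True
        done = all((out / f).exists() for f in _STAGE_OUTPUTS[stage])
        if done and not forced:
            log.info("stage %s: complete, skipped", stage)
            continue
        log.info("stage %s: running", stage)
        _STAGE_FUNCS[stage](config, out, cache)
        forced = True  # downstream stages see refreshed inputs

    manifest = {
        "seed": config.seed,
        "config_sha256": _sha256(out / "config.yaml"),
        "package": "sncelltype 0.1.0",
        "files": {f: _sha256(out / f) for f in RESULT_FILES if (out / f).exists()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
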