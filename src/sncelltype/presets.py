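"""Default synthetic study conditions.

These presets define the conditions under which the package's behaviour
is validated: a substantia-nigra-like atlas whose glial dominance (95%
glia, mostly oligodendrocytes) mirrors the region's real composition, a
matched cortex-like atlas with a 12% glial fraction, a block-LD genome
over the atlas's genes, and trait suites with planted causal gene sets
whose sharing structure exercises the conditional analyses (distinct
cell aetiologies within a trait, shared vs distinct risk between traits,
and non-reciprocal subsumption).
"""

from __future__ import annotations

import numpy as np

from .atlas import ClusterParams, QcThresholds
from .synth import AtlasSimSpec, GwasSimSpec, PpiSimSpec

# SN cell types; ODC dominates the glia as in human SN
SN_TYPES = {
    "ODC": (2160, True),
    "Astro": (300, True),
    "Micro": (200, True),
    "OPC": (205, True),
    "DaN": (60, False),
    "GABA": (75, False),
}
CTX_TYPES = {
    "Ex": (600, False),
    "In": (280, False),
    "Astro_ctx": (60, True),
    "ODC_ctx": (60, True),
}

# default GWAS scale: 20,000 SNPs in 200 independent blocks, N = 50,000
N_BLOCKS = 200
SNPS_PER_BLOCK = 100
WITHIN_BLOCK_R = 0.5
GWAS_N = 50_000

# Per-SNP effect variances (standardized scale). With ~16 SNPs per gene
# at r = 0.5, a causal SNP's expected chi-square is 1 + N * var * 4.75:
# WEAK gives ~1.6 (a diffuse polygenic set enrichment, detectable only in
# aggregate), MID ~11 (top loci reach genome-wide significance, so the
# trait yields conditioning instruments while the LD-score regression
# stays well behaved), STRONG ~31 (dominated by a few large loci).
WEAK_EFFECT_VAR = 2.5e-6
MID_EFFECT_VAR = 4.2e-5
STRONG_EFFECT_VAR = 1.25e-4


def sn_atlas_spec(seed: int = 0, scale: float = 1.0) -> AtlasSimSpec:
    """Nigra-like atlas: 6 types, 95%-abundant ODC, fold-8 markers."""
    counts = {"ODC": 3800, "Astro": 40, "Micro": 40, "OPC": 40, "DaN": 40,
              "GABA": 40}
    glial = {"ODC": True, "Astro": True, "Micro": True, "OPC": True,
             "DaN": False, "GABA": False}
    names = list(counts)
    return AtlasSimSpec(
        n_cell_types=len(names),
        cells_per_type=[max(30, int(round(counts[t] * scale))) for t in names],
        n_genes=1000,
        markers_per_type=25,
        marker_fold_change=8.0,
        baseline_mean=1.0,
        nb_dispersion=2.0,
        mito_fraction_outlier_rate=0.02,
        region_labels={t: "SN" for t in names},
        glial_flags=glial,
        cell_type_names=names,
        seed=seed,
    )


def joint_atlas_spec(seed: int = 0) -> AtlasSimSpec:
    """SN (95.5% glia) plus cortex-like (12% glia) types in one atlas."""
    names = list(SN_TYPES) + list(CTX_TYPES)
    cells = [SN_TYPES[t][0] for t in SN_TYPES] + [CTX_TYPES[t][0] for t in CTX_TYPES]
    glial = {t: SN_TYPES[t][1] for t in SN_TYPES}
    glial.update({t: CTX_TYPES[t][1] for t in CTX_TYPES})
    regions = {t: "SN" for t in SN_TYPES}
    regions.update({t: "CTX" for t in CTX_TYPES})
    return AtlasSimSpec(
        n_cell_types=len(names),
        cells_per_type=cells,
        n_genes=1200,
        markers_per_type=25,
        marker_fold_change=8.0,
        baseline_mean=1.0,
        nb_dispersion=2.0,
        mito_fraction_outlier_rate=0.02,
        region_labels=regions,
        glial_flags=glial,
        cell_type_names=names,
        seed=seed,
    )


def synthetic_qc_thresholds() -> QcThresholds:
    """QC thresholds matched to the simulated sequencing depth.

    The gene-detection floor scales with the ~1,000-gene simulated panel
    (real atlases use 500 genes against >20,000-gene panels); fraction
    thresholds keep their field-standard values.
    """
    return QcThresholds(min_genes_per_cell=300)


def default_cluster_params() -> ClusterParams:
    return ClusterParams(n_hvg=1000, n_pcs=15, snn_k=20, resolution=0.4,
                         min_cluster_size=30)


def gwas_spec_for_genes(
    gene_ids: list[str],
    causal_gene_sets=(),
    gene_sets=None,
    trait2_causal_sets=None,
    shared_fraction: float = 1.0,
    seed: int = 0,
    trait_names=("trait1", "trait2"),
    snps_per_block: int = SNPS_PER_BLOCK,
    within_block_r: float = WITHIN_BLOCK_R,
    n_samples: int = GWAS_N,
    shuffle_genes: bool = True,
    genome_seed: int | None = None,
) -> GwasSimSpec:
    """Block-LD genome over a given gene universe.

    Genes are laid across blocks in a seed-shuffled order so that
    biologically related sets (e.g. one cell type's markers, contiguous
    in atlas order) scatter over many LD blocks, as real gene sets do.
    """
    n_genes = len(gene_ids)
    genes_per_block = 6
    n_blocks = int(np.ceil(n_genes / genes_per_block))
    ids = list(gene_ids)
    pad = n_blocks * genes_per_block - n_genes
    gseed = seed if genome_seed is None else genome_seed
    if shuffle_genes:
        rng = np.random.default_rng(gseed + 7_777)
        ids = [ids[i] for i in rng.permutation(n_genes)]
    ids = ids + [f"FILLER{i:04d}" for i in range(pad)]
    return GwasSimSpec(
        n_blocks=n_blocks,
        snps_per_block=snps_per_block,
        within_block_r=within_block_r,
        n_samples=n_samples,
        genes_per_block=genes_per_block,
        gene_ids=ids,
        gene_sets=gene_sets or {},
        causal_gene_sets=causal_gene_sets,
        trait2_causal_sets=trait2_causal_sets,
        shared_fraction=shared_fraction,
        trait_names=trait_names,
        genome_seed=gseed,
        seed=seed,
    )


def null_gwas_spec(seed: int = 0, n_blocks: int = 500,
                   snps_per_block: int = 40) -> GwasSimSpec:
    """No planted effects; two genes per block, light LD so gene-level
    statistics are close to independent (the regime the competitive
    test's error-rate guarantees refer to)."""
    return GwasSimSpec(
        n_blocks=n_blocks,
        snps_per_block=snps_per_block,
        within_block_r=0.1,
        n_samples=GWAS_N,
        genes_per_block=2,
        seed=seed,
    )


def default_ppi_spec(gene_ids: list[str] | None = None, seed: int = 0) -> PpiSimSpec:
    """Planted-partition PPI: 4 modules x 50 genes."""
    return PpiSimSpec(
        n_modules=4,
        genes_per_module=50,
        p_within=0.3,
        p_between=0.01,
        gene_ids=gene_ids,
        seed=seed,
    )
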