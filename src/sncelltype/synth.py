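"""Synthetic-data generators with planted ground truth.

Every downstream stage of the package (QC/clustering, marker detection,
specificity sets, both association engines, conditional decomposition,
PPI modules, GO enrichment) can be exercised on data produced here, where
the true cell types, causal gene sets, trait-sharing structure and network
communities are known exactly.

All generators are pure functions of their spec, including the seed:
two calls with the same spec return bit-identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import igraph
import numpy as np
import pandas as pd
from scipy import sparse

from .datatypes import GeneAnnotation, GwasStudy, LDBlock, LDPanel

# ---------------------------------------------------------------------------
# single-nuclei expression atlas
# ---------------------------------------------------------------------------

N_MITO_GENES = 10
N_RIBO_GENES = 10


@dataclass
class AtlasSimSpec:
    """Parameters of the negative-binomial cell-by-gene count simulator.

    Counts for gene g in cell c are NB with mean
    ``depth_c * mu_g * fold`` where ``fold = marker_fold_change`` if g is a
    marker of c's true type and 1 otherwise, and variance
    ``mu + mu^2 / nb_dispersion`` (mean/dispersion parameterization).
    Gene baseline means vary log-normally around ``baseline_mean`` and each
    cell carries a log-normal depth factor, so library size and detection
    rate vary between cells as they do in real droplet data.
    """

    n_cell_types: int
    cells_per_type: Sequence[int]
    n_genes: int
    markers_per_type: int = 25
    marker_fold_change: float = 8.0
    baseline_mean: float = 1.0
    nb_dispersion: float = 2.0
    mito_fraction_outlier_rate: float = 0.0
    region_labels: Mapping[str, str] = field(default_factory=dict)
    glial_flags: Mapping[str, bool] = field(default_factory=dict)
    cell_type_names: Sequence[str] | None = None
    gene_mean_sigma: float = 0.5
    depth_sigma: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cells_per_type) != self.n_cell_types:
            raise ValueError("cells_per_type length must equal n_cell_types")
        if self.cell_type_names is None:
            self.cell_type_names = [f"type{i}" for i in range(self.n_cell_types)]
        if len(self.cell_type_names) != self.n_cell_types:
            raise ValueError("cell_type_names length must equal n_cell_types")
        reserved = N_MITO_GENES + N_RIBO_GENES
        if self.markers_per_type * self.n_cell_types > self.n_genes - reserved:
            raise ValueError(
                "markers_per_type x n_cell_types exceeds available genes "
                f"(n_genes minus {reserved} mito/ribo genes)"
            )
        if not 0.0 <= self.mito_fraction_outlier_rate <= 1.0:
            raise ValueError("mito_fraction_outlier_rate must be in [0, 1]")
        for name, val in [
            ("marker_fold_change", self.marker_fold_change),
            ("baseline_mean", self.baseline_mean),
            ("nb_dispersion", self.nb_dispersion),
        ]:
            if val <= 0:
                raise ValueError(f"{name} must be positive")


def simulate_atlas(spec: AtlasSimSpec) -> ad.AnnData:
    """Draw a UMI count atlas with planted cell types.

    Returns an AnnData whose ``obs`` carries the ground truth per cell
    (``true_type``, ``region``, ``glial``, ``sample``) and whose ``var``
    flags mitochondrial/ribosomal genes. Marker genes of each type are
    recorded in ``uns['true_markers']``.
    """
    rng = np.random.default_rng(spec.seed)
    n_cells = int(np.sum(spec.cells_per_type))
    names = list(spec.cell_type_names)

    gene_ids = (
        [f"MT-{i}" for i in range(N_MITO_GENES)]
        + [f"RPL{i}" for i in range(N_RIBO_GENES)]
        + [f"G{i:05d}" for i in range(spec.n_genes - N_MITO_GENES - N_RIBO_GENES)]
    )
    mito = np.zeros(spec.n_genes, dtype=bool)
    mito[:N_MITO_GENES] = True
    ribo = np.zeros(spec.n_genes, dtype=bool)
    ribo[N_MITO_GENES : N_MITO_GENES + N_RIBO_GENES] = True

    # gene baseline means: log-normal spread around baseline_mean
    s = spec.gene_mean_sigma
    gene_mean = spec.baseline_mean * rng.lognormal(-0.5 * s * s, s, spec.n_genes)

    # marker blocks, laid out after the mito/ribo genes
    reserved = N_MITO_GENES + N_RIBO_GENES
    true_markers: dict[str, list[str]] = {}
    marker_of = np.full(spec.n_genes, -1, dtype=int)
    for t in range(spec.n_cell_types):
        lo = reserved + t * spec.markers_per_type
        hi = lo + spec.markers_per_type
        marker_of[lo:hi] = t
        true_markers[names[t]] = gene_ids[lo:hi]

    type_idx = np.repeat(np.arange(spec.n_cell_types), spec.cells_per_type)
    depth = rng.lognormal(-0.5 * spec.depth_sigma**2, spec.depth_sigma, n_cells)

    mu = np.outer(depth, gene_mean)
    for t in range(spec.n_cell_types):
        rows = type_idx == t
        cols = marker_of == t
        mu[np.ix_(rows, cols)] *= spec.marker_fold_change

    # mito outlier cells: inflate mitochondrial gene means well past the
    # 5% QC threshold
    outlier = rng.random(n_cells) < spec.mito_fraction_outlier_rate
    if outlier.any():
        mu[np.ix_(outlier, mito)] *= 30.0

    theta = spec.nb_dispersion
    lam = rng.gamma(shape=theta, scale=mu / theta)
    counts = rng.poisson(lam).astype(np.int64)

    obs = pd.DataFrame(
        {
            "true_type": pd.Categorical([names[t] for t in type_idx]),
            "region": [spec.region_labels.get(names[t], "region1") for t in type_idx],
            "glial": [bool(spec.glial_flags.get(names[t], False)) for t in type_idx],
            "mito_outlier": outlier,
        },
        index=[f"cell_{i:06d}" for i in range(n_cells)],
    )
    # two library preps per region, assigned at random
    obs["sample"] = [
        f"{r}_s{1 + int(b)}" for r, b in zip(obs["region"], rng.random(n_cells) < 0.5)
    ]
    var = pd.DataFrame({"mito": mito, "ribo": ribo}, index=gene_ids)

    adata = ad.AnnData(X=sparse.csr_matrix(counts), obs=obs, var=var)
    adata.uns["true_markers"] = true_markers
    return adata


# ---------------------------------------------------------------------------
# GWAS summary statistics under a block-LD additive model
# ---------------------------------------------------------------------------

SNP_SPACING_BP = 10_000
BLOCK_GAP_BP = 500_000


@dataclass
class GwasSimSpec:
    """Parameters of the summary-statistic simulator.

    Per LD block with correlation matrix R, the z-vector is drawn from
    ``MVN(R @ (sqrt(N) * beta), R)`` — the standard linear-model
    approximation for GWAS summary statistics. ``beta`` (standardized
    per-SNP effects) is nonzero only at SNPs of genes belonging to the
    ``causal_gene_sets``; each causal SNP's effect is N(0, effect_var).

    If ``trait2_causal_sets`` is given a correlated second trait is
    simulated: gene sets causal in both traits share identical effects for
    a ``shared_fraction`` of their genes (scaled to the second trait's
    effect variance), the remainder and trait-exclusive sets are drawn
    independently.
    """

    n_blocks: int
    snps_per_block: int
    within_block_r: float
    n_samples: int
    genes_per_block: int = 4
    gene_sets: Mapping[str, Sequence[str]] = field(default_factory=dict)
    causal_gene_sets: Sequence[tuple[str, float]] = ()
    trait2_causal_sets: Sequence[tuple[str, float]] | None = None
    shared_fraction: float = 1.0
    n_samples2: int | None = None
    trait_names: Sequence[str] = ("trait1", "trait2")
    gene_ids: Sequence[str] | None = None
    genome_seed: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.within_block_r < 1.0:
            raise ValueError("within_block_r must be in [0, 1)")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must be in [0, 1]")
        for sid, var in list(self.causal_gene_sets) + list(
            self.trait2_causal_sets or []
        ):
            if var < 0:
                raise ValueError(f"effect variance for set {sid!r} is negative")
        if 2 * self.genes_per_block > self.snps_per_block:
            raise ValueError("need at least two SNPs per gene per block")
        n_genes = self.n_blocks * self.genes_per_block
        if self.gene_ids is not None and len(self.gene_ids) != n_genes:
            raise ValueError(
                f"gene_ids must have length n_blocks*genes_per_block={n_genes}"
            )


@dataclass
class SimulatedGwas:
    """Output bundle of :func:`simulate_gwas`: the studies plus the exact
    inputs (LD panel, gene annotation, gene sets, true effects) they were
    generated from."""

    studies: list[GwasStudy]
    panel: LDPanel
    genes: GeneAnnotation
    gene_sets: dict[str, list[str]]
    true_beta: dict[str, pd.Series]
    gene_snps: dict[str, list[str]]

    @property
    def study(self) -> GwasStudy:
        return self.studies[0]


def _block_matrix(m: int, r: float) -> np.ndarray:
    R = np.full((m, m), r)
    np.fill_diagonal(R, 1.0)
    return R


def simulate_gwas(spec: GwasSimSpec) -> SimulatedGwas:
    """Simulate one trait (or a correlated pair) over a block-LD genome.

    The synthetic genome is one chromosome of ``n_blocks`` independent LD
    blocks, SNPs spaced 10 kb apart with 500 kb gaps between blocks, and
    ``genes_per_block`` genes tiling each block's SNPs contiguously with
    variable extents (at least two SNPs each), so gene length and SNP
    count vary as they do in real annotations. The genome layout depends
    only on ``genome_seed`` (default: ``seed``), so traits simulated with
    different seeds can share one genome.
    """
    rng = np.random.default_rng(spec.seed)
    genome_rng = np.random.default_rng(
        spec.seed if spec.genome_seed is None else spec.genome_seed
    )
    m = spec.snps_per_block
    R = _block_matrix(m, spec.within_block_r)
    # exchangeable correlation with r in [0,1) is positive definite
    L = np.linalg.cholesky(R)

    n_genes = spec.n_blocks * spec.genes_per_block
    gene_ids = (
        list(spec.gene_ids)
        if spec.gene_ids is not None
        else [f"G{i:05d}" for i in range(n_genes)]
    )

    snp_rows = []
    gene_rows = []
    gene_snps: dict[str, list[str]] = {}
    blocks: list[LDBlock] = []
    block_span = m * SNP_SPACING_BP + BLOCK_GAP_BP
    g_per = spec.genes_per_block
    for b in range(spec.n_blocks):
        ids = np.array([f"rs{b}_{i}" for i in range(m)], dtype=object)
        pos = b * block_span + np.arange(m) * SNP_SPACING_BP + 1  # 1-based
        blocks.append(LDBlock(snps=ids, R=R))
        for i in range(m):
            snp_rows.append((ids[i], "1", int(pos[i])))
        sizes = 2 + genome_rng.multinomial(m - 2 * g_per, np.full(g_per, 1.0 / g_per))
        offsets = np.concatenate([[0], np.cumsum(sizes)])
        for j in range(g_per):
            g = gene_ids[b * g_per + j]
            lo, hi = int(offsets[j]), int(offsets[j + 1])
            gene_snps[g] = list(ids[lo:hi])
            # 0-based half-open interval covering exactly these SNPs
            gene_rows.append((g, "1", int(pos[lo]) - 1, int(pos[hi - 1])))

    snp_df = pd.DataFrame(snp_rows, columns=["SNP", "CHR", "BP"])
    genes = GeneAnnotation(
        pd.DataFrame(gene_rows, columns=["gene", "CHR", "start", "end"])
    )

    gene_sets = {k: list(v) for k, v in spec.gene_sets.items()}
    for sid, _ in list(spec.causal_gene_sets) + list(spec.trait2_causal_sets or []):
        if sid not in gene_sets:
            raise ValueError(f"causal gene set {sid!r} not present in gene_sets")
        unknown = set(gene_sets[sid]) - set(gene_ids)
        if unknown:
            raise ValueError(f"set {sid!r} names genes outside the genome: {unknown}")

    snp_index = pd.Index(snp_df["SNP"])

    def _draw_beta(causal: Sequence[tuple[str, float]], rng) -> pd.Series:
        beta = pd.Series(0.0, index=snp_index)
        for sid, var in causal:
            if var == 0:
                continue
            for g in gene_sets[sid]:
                ids = gene_snps[g]
                beta[ids] += rng.normal(0.0, np.sqrt(var), len(ids))
        return beta

    traits = [(spec.trait_names[0], list(spec.causal_gene_sets), spec.n_samples)]
    if spec.trait2_causal_sets is not None:
        traits.append(
            (
                spec.trait_names[1],
                list(spec.trait2_causal_sets),
                spec.n_samples2 or spec.n_samples,
            )
        )

    betas: dict[str, pd.Series] = {}
    if len(traits) == 1:
        betas[traits[0][0]] = _draw_beta(traits[0][1], rng)
    else:
        # split shared sets into an identical-effect part and independent parts
        sets1 = dict(traits[0][1])
        sets2 = dict(traits[1][1])
        shared_ids = sorted(set(sets1) & set(sets2))
        beta1 = _draw_beta(
            [(s, v) for s, v in sets1.items() if s not in shared_ids], rng
        )
        beta2 = _draw_beta(
            [(s, v) for s, v in sets2.items() if s not in shared_ids], rng
        )
        for sid in shared_ids:
            genes_in = list(gene_sets[sid])
            n_shared = int(round(spec.shared_fraction * len(genes_in)))
            shared_genes = list(
                rng.choice(genes_in, size=n_shared, replace=False)
            )
            v1, v2 = sets1[sid], sets2[sid]
            for g in genes_in:
                ids = gene_snps[g]
                if g in shared_genes:
                    u = rng.normal(0.0, 1.0, len(ids))
                    beta1[ids] += np.sqrt(v1) * u
                    beta2[ids] += np.sqrt(v2) * u
                else:
                    beta1[ids] += rng.normal(0.0, np.sqrt(v1), len(ids))
                    beta2[ids] += rng.normal(0.0, np.sqrt(v2), len(ids))
        betas[traits[0][0]] = beta1
        betas[traits[1][0]] = beta2

    studies = []
    for name, _, n_samp in traits:
        beta = betas[name].to_numpy()
        z = np.empty(spec.n_blocks * m)
        sqn = np.sqrt(n_samp)
        for b in range(spec.n_blocks):
            sl = slice(b * m, (b + 1) * m)
            eps = rng.standard_normal(m)
            z[sl] = R @ (sqn * beta[sl]) + L @ eps
        df = snp_df.copy()
        df["A1"] = "A"
        df["A2"] = "G"
        df["Z"] = z
        df["N"] = n_samp
        studies.append(GwasStudy(df, trait=name))

    return SimulatedGwas(
        studies=studies,
        panel=LDPanel(blocks),
        genes=genes,
        gene_sets=gene_sets,
        true_beta=betas,
        gene_snps=gene_snps,
    )


# ---------------------------------------------------------------------------
# planted-partition PPI networks
# ---------------------------------------------------------------------------


@dataclass
class PpiSimSpec:
    """Planted-partition graph: ``n_modules`` communities of
    ``genes_per_module`` nodes, edge probability ``p_within`` inside a
    community and ``p_between`` across."""

    n_modules: int
    genes_per_module: int
    p_within: float
    p_between: float
    gene_ids: Sequence[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name, p in [("p_within", self.p_within), ("p_between", self.p_between)]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_modules > 1 and self.p_within <= self.p_between:
            raise ValueError("p_within must exceed p_between")
        n = self.n_modules * self.genes_per_module
        if self.gene_ids is not None and len(self.gene_ids) != n:
            raise ValueError(f"gene_ids must have length {n}")


def simulate_ppi(spec: PpiSimSpec) -> tuple[igraph.Graph, np.ndarray]:
    """Sample an undirected simple graph with planted modules.

    Returns the graph (node names in ``vs['name']``) and the true module
    label per node.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_modules * spec.genes_per_module
    labels = np.repeat(np.arange(spec.n_modules), spec.genes_per_module)
    names = (
        list(spec.gene_ids)
        if spec.gene_ids is not None
        else [f"G{i:05d}" for i in range(n)]
    )
    iu, ju = np.triu_indices(n, k=1)
    p_edge = np.where(labels[iu] == labels[ju], spec.p_within, spec.p_between)
    keep = rng.random(len(p_edge)) < p_edge
    edges = list(zip(iu[keep].tolist(), ju[keep].tolist()))
    g = igraph.Graph(n=n, edges=edges, directed=False)
    g.vs["name"] = names
    return g, labels


# ---------------------------------------------------------------------------
# synthetic GO term -> gene maps
# ---------------------------------------------------------------------------


def simulate_go(
    universe: Sequence[str],
    n_terms: int,
    term_size_range: tuple[int, int],
    seed: int = 0,
    seeded_terms: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, list[str]]:
    """Random GO-like term->gene map over a gene universe.

    ``seeded_terms`` lets a term be planted to coincide with a known gene
    set (e.g. a PPI module) for enrichment power tests.
    """
    if len(universe) == 0:
        raise ValueError("universe is empty")
    lo, hi = term_size_range
    if hi > len(universe):
        raise ValueError("term size range exceeds universe size")
    if lo < 1 or lo > hi:
        raise ValueError("invalid term size range")
    rng = np.random.default_rng(seed)
    universe = list(universe)
    terms: dict[str, list[str]] = {}
    for i in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        terms[f"GO:{i:07d}"] = sorted(rng.choice(universe, size, replace=False))
    for name, genes in (seeded_terms or {}).items():
        missing = set(genes) - set(universe)
        if missing:
            raise ValueError(f"seeded term {name!r} has genes outside universe")
        terms[name] = sorted(genes)
    return terms
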