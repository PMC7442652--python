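"""Atlas QC, normalization with covariate regression, and SNN/Louvain clustering.

The processing chain mirrors standard droplet single-nuclei practice:
genes kept if detected in a minimum number of nuclei; nuclei filtered on
detected genes, UMI cap, and mitochondrial/ribosomal fractions; depth
normalization and log transform; per-gene linear residualization on
technical covariates; highly-variable-gene selection; PCA; shared-nearest
-neighbour graph with Jaccard edge weights; multi-level modularity
(Louvain) clustering; and removal of clusters below a minimum size.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import anndata as ad
import igraph
import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors


class EmptyAtlasError(ValueError):
    """Raised when QC filtering removes every cell or every gene."""


@dataclass
class QcThresholds:
    """Quality-control thresholds.

    ``max_umi`` may be a scalar cap, a per-sample mapping, or None, in
    which case each sample's cap defaults to its 99.5th UMI percentile
    (the cap is sample-dependent in droplet data; the resolved values are
    recorded in the QC report and can be passed back in for reproducible
    re-filtering).
    """

    min_cells_per_gene: int = 3
    min_genes_per_cell: int = 500
    max_umi: float | Mapping[str, float] | None = None
    max_mito: float = 0.05
    max_ribo: float = 0.05
    umi_percentile: float = 99.5

    def __post_init__(self) -> None:
        if self.min_cells_per_gene <= 0 or self.min_genes_per_cell <= 0:
            raise ValueError("count thresholds must be positive")
        if self.max_mito <= 0 or self.max_ribo <= 0:
            raise ValueError("fraction thresholds must be positive")


@dataclass
class QcReport:
    n_cells_in: int
    n_genes_in: int
    n_cells_out: int
    n_genes_out: int
    genes_removed_low_detection: int
    cells_removed_low_genes: int
    cells_removed_high_umi: int
    cells_removed_mito: int
    cells_removed_ribo: int
    resolved_max_umi: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        d = asdict(self)
        d.pop("resolved_max_umi")
        return pd.DataFrame({"metric": list(d), "value": list(d.values())})


def _cell_metrics(adata: ad.AnnData) -> pd.DataFrame:
    X = sparse.csr_matrix(adata.X)
    n_umi = np.asarray(X.sum(axis=1)).ravel()
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    mito = np.asarray(adata.var["mito"], dtype=bool)
    ribo = np.asarray(adata.var["ribo"], dtype=bool)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(
            n_umi > 0, np.asarray(X[:, mito].sum(axis=1)).ravel() / n_umi, 0.0
        )
        ribo_frac = np.where(
            n_umi > 0, np.asarray(X[:, ribo].sum(axis=1)).ravel() / n_umi, 0.0
        )
    return pd.DataFrame(
        {
            "n_umi": n_umi,
            "n_genes": n_genes,
            "mito_fraction": mito_frac,
            "ribo_fraction": ribo_frac,
        },
        index=adata.obs_names,
    )


def qc_filter(
    adata: ad.AnnData, thr: QcThresholds | None = None
) -> tuple[ad.AnnData, QcReport]:
    """Filter genes then cells; returns the filtered atlas and a report.

    Genes are kept iff nonzero in at least ``min_cells_per_gene`` cells of
    the input; cells are then kept iff they satisfy all per-cell criteria.
    Cell metrics (``n_umi``, ``n_genes``, mito/ribo fractions) are computed
    on the input matrix before the gene filter and stored in ``obs``.
    """
    thr = thr or QcThresholds()
    metrics = _cell_metrics(adata)

    X = sparse.csc_matrix(adata.X)
    cells_per_gene = np.asarray((X > 0).sum(axis=0)).ravel()
    gene_keep = cells_per_gene >= thr.min_cells_per_gene

    samples = (
        adata.obs["sample"].astype(str)
        if "sample" in adata.obs
        else pd.Series("all", index=adata.obs_names)
    )
    if thr.max_umi is None:
        caps = {
            s: float(np.percentile(metrics.loc[samples == s, "n_umi"], thr.umi_percentile))
            for s in samples.unique()
        }
    elif isinstance(thr.max_umi, Mapping):
        caps = {s: float(thr.max_umi[s]) for s in samples.unique()}
    else:
        caps = {s: float(thr.max_umi) for s in samples.unique()}
    cap_per_cell = samples.map(caps).to_numpy(dtype=float)

    ok_genes = metrics["n_genes"].to_numpy() >= thr.min_genes_per_cell
    ok_umi = metrics["n_umi"].to_numpy() <= cap_per_cell
    ok_mito = metrics["mito_fraction"].to_numpy() <= thr.max_mito
    ok_ribo = metrics["ribo_fraction"].to_numpy() <= thr.max_ribo
    cell_keep = ok_genes & ok_umi & ok_mito & ok_ribo

    report = QcReport(
        n_cells_in=adata.n_obs,
        n_genes_in=adata.n_vars,
        n_cells_out=int(cell_keep.sum()),
        n_genes_out=int(gene_keep.sum()),
        genes_removed_low_detection=int((~gene_keep).sum()),
        cells_removed_low_genes=int((~ok_genes).sum()),
        cells_removed_high_umi=int((~ok_umi).sum()),
        cells_removed_mito=int((~ok_mito).sum()),
        cells_removed_ribo=int((~ok_ribo).sum()),
        resolved_max_umi=caps,
    )
    if report.n_cells_out == 0 or report.n_genes_out == 0:
        raise EmptyAtlasError(
            f"QC removed everything: {report.n_cells_out} cells, "
            f"{report.n_genes_out} genes remain"
        )
    out = adata[cell_keep, gene_keep].copy()
    for col in metrics.columns:
        out.obs[col] = metrics.loc[cell_keep, col].to_numpy()
    return out, report


def normalize_and_regress(
    adata: ad.AnnData,
    covariates: Sequence[str] = ("n_umi", "mito_fraction", "ribo_fraction"),
    scale: float = 1e4,
    batch_key: str | None = None,
) -> ad.AnnData:
    """Depth-normalize, log-transform, residualize covariates, unit-scale.

    Each cell is scaled to ``scale`` total counts and log1p-transformed
    (layer ``"lognorm"``); each gene is then residualized by OLS on the
    given per-cell covariates (plus sample-indicator dummies when
    ``batch_key`` is set) and centered/unit-scaled (layer ``"scaled"``).
    Deterministic; genes with zero variance scale to all-zeros.
    """
    X = sparse.csr_matrix(adata.X).astype(float)
    depth = np.asarray(X.sum(axis=1)).ravel()
    if (depth == 0).any():
        raise ValueError("zero-depth cell encountered; run qc_filter first")
    norm = X.multiply(scale / depth[:, None]).tocsr()
    lognorm = norm.copy()
    lognorm.data = np.log1p(lognorm.data)
    adata.layers["lognorm"] = lognorm

    Y = np.asarray(lognorm.todense())
    cols = [np.ones(adata.n_obs)]
    for c in covariates:
        if c not in adata.obs:
            raise KeyError(f"covariate {c!r} not in obs (run qc_filter first)")
        v = adata.obs[c].to_numpy(dtype=float)
        sd = v.std()
        cols.append((v - v.mean()) / sd if sd > 0 else np.zeros_like(v))
    if batch_key is not None:
        dummies = pd.get_dummies(adata.obs[batch_key], drop_first=True)
        for c in dummies.columns:
            cols.append(dummies[c].to_numpy(dtype=float))
    C = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(C, Y, rcond=None)
    resid = Y - C @ beta

    resid -= resid.mean(axis=0)
    sd = resid.std(axis=0)
    sd[sd == 0] = 1.0
    adata.layers["scaled"] = resid / sd
    return adata


@dataclass
class ClusterParams:
    """SNN/Louvain clustering parameters.

    Resolution defaults inside the 0.4-0.8 range used for selecting the
    final partition; clusters smaller than ``min_cluster_size`` cells are
    dropped and their cells flagged unassigned.
    """

    n_hvg: int = 2000
    n_pcs: int = 15
    snn_k: int = 20
    resolution: float = 0.5
    min_cluster_size: int = 30
    snn_prune: float = 1.0 / 15.0


UNASSIGNED = "unassigned"


def _snn_graph(pcs: np.ndarray, k: int, prune: float) -> igraph.Graph:
    """Shared-nearest-neighbour graph with Jaccard edge weights.

    Neighbour sets include the cell itself; edges with Jaccard weight
    below ``prune`` are removed.
    """
    n = pcs.shape[0]
    nn = NearestNeighbors(n_neighbors=k).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    rows = np.repeat(np.arange(n), k)
    A = sparse.csr_matrix(
        (np.ones(n * k), (rows, idx.ravel())), shape=(n, n), dtype=np.int32
    )
    A = A.maximum(sparse.eye(n, format="csr", dtype=np.int32))
    shared = (A @ A.T).tocoo()
    mask = shared.row < shared.col
    r, c, s = shared.row[mask], shared.col[mask], shared.data[mask].astype(float)
    sizes = np.asarray(A.sum(axis=1)).ravel()
    union = sizes[r] + sizes[c] - s
    jac = s / union
    keep = jac >= prune
    g = igraph.Graph(
        n=n, edges=list(zip(r[keep].tolist(), c[keep].tolist())), directed=False
    )
    g.es["weight"] = jac[keep].tolist()
    return g


def cluster(
    adata: ad.AnnData, params: ClusterParams | None = None, seed: int = 0
) -> ad.AnnData:
    """HVG -> PCA -> SNN -> Louvain; writes ``obs['cluster']``.

    Cluster labels are strings "c1", "c2", ... ordered by decreasing
    size; cells of clusters below ``min_cluster_size`` get the label
    ``"unassigned"``. Deterministic for a fixed seed.
    """
    params = params or ClusterParams()
    if "scaled" not in adata.layers:
        raise ValueError("run normalize_and_regress before cluster")
    if params.snn_k >= adata.n_obs:
        raise ValueError("snn_k must be smaller than the number of cells")

    lognorm = np.asarray(sparse.csr_matrix(adata.layers["lognorm"]).todense())
    var = lognorm.var(axis=0)
    n_hvg = min(params.n_hvg, adata.n_vars)
    hvg = np.sort(np.argsort(var)[::-1][:n_hvg])
    adata.var["highly_variable"] = np.isin(np.arange(adata.n_vars), hvg)

    X = np.asarray(adata.layers["scaled"])[:, hvg]
    n_pcs = min(params.n_pcs, min(X.shape) - 1)
    pca = PCA(n_components=n_pcs, svd_solver="full", random_state=0)
    pcs = pca.fit_transform(X)
    adata.obsm["X_pca"] = pcs

    g = _snn_graph(pcs, params.snn_k, params.snn_prune)
    igraph.set_random_number_generator(random.Random(seed))
    part = g.community_multilevel(weights="weight", resolution=params.resolution)
    membership = np.asarray(part.membership)

    labels, counts = np.unique(membership, return_counts=True)
    order = labels[np.argsort(-counts)]
    name_of: dict[int, str] = {}
    nxt = 1
    for lab in order:
        size = counts[labels == lab][0]
        if size >= params.min_cluster_size:
            name_of[lab] = f"c{nxt}"
            nxt += 1
        else:
            name_of[lab] = UNASSIGNED
    adata.obs["cluster"] = pd.Categorical([name_of[m] for m in membership])
    adata.uns["cluster_modularity"] = float(
        g.modularity(membership, weights="weight")
    )
    return adata


def assigned_mask(adata: ad.AnnData) -> np.ndarray:
    return (adata.obs["cluster"] != UNASSIGNED).to_numpy()
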