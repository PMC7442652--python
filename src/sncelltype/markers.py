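"""Marker detection, cell-type specificity scores, and composition matching.

Markers: per gene, a negative-binomial regression of UMI counts on an
in-cluster indicator with a log-depth offset and a likelihood-ratio test,
after prefiltering on log fold change (>= 0.25 natural log) and in-cluster
detection (>= 25% of cells) — the convention of droplet-data marker tests.

Specificity: score(g, c) = mean depth-normalized expression of gene g in
cell type c divided by the sum of those means over all types (EWCE /
LDSC-SEG convention); the top decile of each type's scores forms that
type's gene set.

Composition matching (:func:`homogenize_regions`) resamples two regional
atlases so both carry the same glial proportion, removing neuron/glia
composition differences before cross-region comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import sparse, stats

from .atlas import UNASSIGNED

MARKER_COLUMNS = ["gene", "cluster", "logFC", "pct_in", "pct_out", "p", "q", "method"]


def _counts_depth(adata: ad.AnnData) -> tuple[sparse.csr_matrix, np.ndarray]:
    X = sparse.csr_matrix(adata.X).astype(float)
    depth = np.asarray(X.sum(axis=1)).ravel()
    return X, depth


def _nb_lrt(y: np.ndarray, group: np.ndarray, offset: np.ndarray) -> tuple[float, str]:
    """Likelihood-ratio p for a group effect under a NB GLM with offset.

    Dispersion is a gene-wise method-of-moments estimate from the Pearson
    residuals of the group-means Poisson fit; a non-positive estimate
    falls back to a Poisson LRT (flagged "poisson").
    """
    exposure = np.exp(offset)
    mu0 = np.full_like(y, y.sum() / exposure.sum()) * exposure
    mu1 = np.where(
        group,
        y[group].sum() / exposure[group].sum(),
        y[~group].sum() / exposure[~group].sum(),
    ) * exposure
    # moment estimate of alpha in var = mu + alpha mu^2
    alpha = float(np.sum((y - mu1) ** 2 - mu1) / np.sum(mu1**2))
    X = sm.add_constant(group.astype(float))
    if alpha <= 0:
        fam = sm.families.Poisson()
        method = "poisson"
    else:
        fam = sm.families.NegativeBinomial(alpha=alpha)
        method = "nb"
    try:
        ll1 = sm.GLM(y, X, family=fam, offset=offset).fit().llf
        ll0 = sm.GLM(y, X[:, :1], family=fam, offset=offset).fit().llf
    except Exception:
        fam, method = sm.families.Poisson(), "poisson"
        ll1 = sm.GLM(y, X, family=fam, offset=offset).fit().llf
        ll0 = sm.GLM(y, X[:, :1], family=fam, offset=offset).fit().llf
    lr = max(0.0, 2.0 * (ll1 - ll0))
    return float(stats.chi2.sf(lr, df=1)), method


def find_markers(
    adata: ad.AnnData,
    cluster: str,
    background: str | list[str] | None = None,
    cluster_key: str = "cluster",
    min_logfc: float = 0.25,
    min_pct: float = 0.25,
    scale: float = 1e4,
) -> pd.DataFrame:
    """One-vs-rest marker genes for ``cluster``.

    ``background`` restricts the comparison cells to the given sibling
    cluster(s); default is all other assigned cells. Only genes passing
    the logFC/detection prefilter are tested; BH-FDR is applied across the
    tested genes.
    """
    if cluster_key not in adata.obs:
        raise ValueError(f"no {cluster_key!r} labels; run cluster first")
    labels = adata.obs[cluster_key].astype(str)
    if cluster not in set(labels):
        raise ValueError(f"cluster {cluster!r} not present")
    in_mask = (labels == cluster).to_numpy()
    if background is None:
        out_mask = (~in_mask) & (labels != UNASSIGNED).to_numpy()
    else:
        bg = [background] if isinstance(background, str) else list(background)
        missing = set(bg) - set(labels)
        if missing:
            raise ValueError(f"background clusters not present: {missing}")
        out_mask = labels.isin(bg).to_numpy() & ~in_mask
    if out_mask.sum() == 0:
        raise ValueError("empty background for marker test")

    X, depth = _counts_depth(adata)
    norm = X.multiply(scale / depth[:, None]).tocsr()
    mean_in = np.asarray(norm[in_mask].mean(axis=0)).ravel()
    mean_out = np.asarray(norm[out_mask].mean(axis=0)).ravel()
    eps = 1e-9
    logfc = np.log(mean_in + eps) - np.log(mean_out + eps)
    pct_in = np.asarray((X[in_mask] > 0).mean(axis=0)).ravel()
    pct_out = np.asarray((X[out_mask] > 0).mean(axis=0)).ravel()

    test = (logfc >= min_logfc) & (pct_in >= min_pct)
    rows = []
    cells = in_mask | out_mask
    offset = np.log(depth[cells])
    group = in_mask[cells]
    dense = np.asarray(X[cells].todense())
    for gi in np.flatnonzero(test):
        p, method = _nb_lrt(dense[:, gi], group, offset)
        rows.append(
            (
                adata.var_names[gi],
                cluster,
                float(logfc[gi]),
                float(pct_in[gi]),
                float(pct_out[gi]),
                p,
                np.nan,
                method,
            )
        )
    res = pd.DataFrame(rows, columns=MARKER_COLUMNS)
    if len(res):
        # BH-FDR with the full gene panel as the family (the Seurat
        # convention): genes excluded by the prefilter count as
        # non-discoveries, which keeps FDR control despite the
        # effect-size selection step
        res["q"] = _bh_full_family(res["p"].to_numpy(), adata.n_vars)
        res = res.sort_values("p", kind="mergesort").reset_index(drop=True)
    return res


def _bh_full_family(p: np.ndarray, m_total: int) -> np.ndarray:
    """BH step-up q-values with family size ``m_total`` >= len(p);
    untested family members are treated as p = 1."""
    order = np.argsort(p)
    ranks = np.arange(1, len(p) + 1)
    q_sorted = p[order] * m_total / ranks
    q_sorted = np.minimum(1.0, np.minimum.accumulate(q_sorted[::-1])[::-1])
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def find_all_markers(adata: ad.AnnData, cluster_key: str = "cluster", **kw) -> pd.DataFrame:
    """Markers for every assigned cluster (one-vs-rest)."""
    labels = [
        c for c in adata.obs[cluster_key].astype(str).unique() if c != UNASSIGNED
    ]
    out = [find_markers(adata, c, cluster_key=cluster_key, **kw) for c in sorted(labels)]
    return pd.concat(out, ignore_index=True) if out else pd.DataFrame(columns=MARKER_COLUMNS)


@dataclass
class SpecificityTable:
    """Gene-by-cell-type specificity scores and derived top-decile sets.

    ``scores`` rows sum to 1; ``gene_sets[c]`` holds the genes in the top
    decile of type c's specificity.
    """

    scores: pd.DataFrame
    gene_sets: dict[str, list[str]]
    decile: float = 0.10


def specificity(
    adata: ad.AnnData,
    cluster_key: str = "cluster",
    scale: float = 1e4,
    decile: float = 0.10,
) -> SpecificityTable:
    """Mean-expression-proportion specificity per gene and cell type.

    Uses depth-normalized (linear) expression; genes with zero total mean
    are dropped. Requires at least two assigned clusters.
    """
    labels = adata.obs[cluster_key].astype(str)
    types = sorted(c for c in labels.unique() if c != UNASSIGNED)
    if len(types) < 2:
        raise ValueError("specificity requires at least two cell types")
    X, depth = _counts_depth(adata)
    norm = X.multiply(scale / depth[:, None]).tocsr()
    means = np.column_stack(
        [np.asarray(norm[(labels == t).to_numpy()].mean(axis=0)).ravel() for t in types]
    )
    total = means.sum(axis=1)
    keep = total > 0
    scores = pd.DataFrame(
        means[keep] / total[keep, None], index=adata.var_names[keep], columns=types
    )
    n_top = max(1, int(np.ceil(decile * scores.shape[0])))
    gene_sets = {
        t: sorted(scores[t].nlargest(n_top).index.tolist()) for t in types
    }
    return SpecificityTable(scores=scores, gene_sets=gene_sets, decile=decile)


def homogenize_regions(
    adata1: ad.AnnData,
    adata2: ad.AnnData,
    seed: int = 0,
    glial_key: str = "glial",
) -> tuple[ad.AnnData, ad.AnnData]:
    """Downsample two regional atlases to a common glial proportion.

    The target fraction is the pooled glial fraction over both regions.
    Within each region the over-represented compartment (glia or neurons)
    is downsampled uniformly without replacement until the region matches
    the target within one cell. Seeded and reproducible.
    """
    rng = np.random.default_rng(seed)

    def _resample(adata: ad.AnnData, target: float) -> ad.AnnData:
        glial = np.asarray(adata.obs[glial_key], dtype=bool)
        n_g, n_n = int(glial.sum()), int((~glial).sum())
        if n_g == 0 or n_n == 0:
            raise ValueError("region lacks a glial or neuronal compartment")
        frac = n_g / (n_g + n_n)
        if abs(frac - target) * (n_g + n_n) < 1.0:
            return adata
        if frac > target:
            keep_g = int(round(target * n_n / (1.0 - target)))
            idx_g = rng.choice(np.flatnonzero(glial), size=keep_g, replace=False)
            keep = np.sort(np.concatenate([idx_g, np.flatnonzero(~glial)]))
        else:
            keep_n = int(round((1.0 - target) * n_g / target))
            idx_n = rng.choice(np.flatnonzero(~glial), size=keep_n, replace=False)
            keep = np.sort(np.concatenate([np.flatnonzero(glial), idx_n]))
        return adata[keep].copy()

    for a in (adata1, adata2):
        if glial_key not in a.obs:
            raise ValueError(f"atlas lacks obs[{glial_key!r}] flags")
    g1 = int(np.asarray(adata1.obs[glial_key], dtype=bool).sum())
    g2 = int(np.asarray(adata2.obs[glial_key], dtype=bool).sum())
    target = (g1 + g2) / (adata1.n_obs + adata2.n_obs)
    return _resample(adata1, target), _resample(adata2, target)
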