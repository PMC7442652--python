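"""Stratified LD-score regression with gene-set annotations.

Categories are built from gene sets by windowed SNP membership; per-SNP
partitioned LD scores l(j, c) = sum of r^2 between SNP j and the
category's SNPs within j's block; the regression fits per-SNP chi-square
on N * l(j, c) across categories with a free intercept, weighted by
1 / max(l_baseline, 1), and obtains coefficient standard errors by a
delete-one-block jackknife over contiguous SNP blocks. The cell-type test
is the one-sided p-value for the target category's coefficient tau > 0;
the conditional variant adds control categories to the design and reads
the target's coefficient p as the shared-vs-distinct verdict.

The baseline is a single all-SNPs category; extra baseline categories can
be supplied for data with functional-category structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GeneAnnotation, GwasStudy, LDPanel
from .geneassoc import map_snps_to_genes

log = logging.getLogger(__name__)

BASELINE = "baseline"


@dataclass
class Annotation:
    """Per-SNP binary category memberships; baseline is all ones."""

    df: pd.DataFrame  # index: SNP; columns: categories (baseline first)
    window_kb: float = 100.0

    def __post_init__(self) -> None:
        self.df = self.df.copy()
        if BASELINE not in self.df.columns:
            self.df.insert(0, BASELINE, 1)
        if not (self.df[BASELINE] == 1).all():
            raise ValueError("baseline category must be all ones")

    @property
    def categories(self) -> list[str]:
        return [c for c in self.df.columns]


def build_annotation(
    gene_sets: dict[str, list[str]],
    genes: GeneAnnotation,
    sumstats: GwasStudy | pd.DataFrame,
    window_kb: float = 100.0,
) -> Annotation:
    """Binary SNP annotation: one category per gene set plus the baseline.

    A SNP belongs to a set's category iff it lies within ``window_kb`` of
    any gene in the set. Empty categories are dropped with a warning.
    """
    df = sumstats.df if isinstance(sumstats, GwasStudy) else sumstats
    snp_map = map_snps_to_genes(df, genes, window_kb=window_kb)
    out = pd.DataFrame({BASELINE: 1}, index=pd.Index(df["SNP"], name="SNP"))
    for name, gset in gene_sets.items():
        members: set = set()
        for g in gset:
            members.update(snp_map.get(g, ()))
        if not members:
            log.warning("annotation category %r is empty; dropped", name)
            continue
        out[name] = out.index.isin(members).astype(int)
    return Annotation(out, window_kb=window_kb)


def ld_scores(annotation: Annotation, panel: LDPanel) -> pd.DataFrame:
    """Partitioned LD scores l(j, c) within blocks; cross-block r^2 = 0.

    SNPs absent from the panel are excluded (counted in the log).
    """
    snps = annotation.df.index
    rows = []
    n_missing = 0
    present = set()
    for b in panel.blocks:
        ids = [s for s in b.snps if s in annotation.df.index]
        present.update(ids)
        if not ids:
            continue
        idx = [int(np.flatnonzero(b.snps == s)[0]) for s in ids]
        R2 = b.R[np.ix_(idx, idx)] ** 2
        A = annotation.df.loc[ids].to_numpy(dtype=float)
        L = R2 @ A
        rows.append(pd.DataFrame(L, index=ids, columns=annotation.df.columns))
    n_missing = len(snps) - len(present)
    if n_missing:
        log.info("%d annotation SNPs absent from LD panel; excluded", n_missing)
    out = pd.concat(rows)
    return out.loc[[s for s in snps if s in present]]


@dataclass
class LdscFit:
    """Coefficients, jackknife SEs and one-sided p per category."""

    tau: pd.Series
    se: pd.Series
    p: pd.Series
    intercept: float
    intercept_se: float
    n_snps: int
    n_blocks_jackknife: int
    target: str | None = None
    verdict: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"tau": self.tau, "se": self.se, "p": self.p})


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    sw = np.sqrt(w)
    return np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)[0]


def fit_stratified(
    study: GwasStudy,
    scores: pd.DataFrame,
    n_jackknife_blocks: int = 200,
) -> LdscFit:
    """Weighted regression of chi-square on N*l(j,c) with a free intercept.

    Jackknife blocks are contiguous runs of SNPs in panel order; their
    count shrinks automatically when SNPs are few. One-sided p-values
    test tau_c > 0 against the jackknife SE.
    """
    cats = [c for c in scores.columns]
    if len(cats) < 2:
        raise ValueError("need baseline plus at least one target category")
    for i, a in enumerate(cats):
        for b in cats[i + 1 :]:
            if np.array_equal(scores[a].to_numpy(), scores[b].to_numpy()):
                raise ValueError(f"duplicate annotation categories: {a!r}, {b!r}")
    zmap = study.zmap()
    common = [s for s in scores.index if s in zmap.index]
    if len(common) < 10 * (len(cats) + 1):
        raise ValueError("too few SNPs for the number of categories")
    L = scores.loc[common].to_numpy(dtype=float)
    chi2 = zmap[common].to_numpy() ** 2
    N = study.df.set_index("SNP").loc[common, "N"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(common)), N[:, None] * L])
    w = 1.0 / np.maximum(L[:, 0], 1.0)

    n_jk = int(min(n_jackknife_blocks, max(2, len(common) // 50)))
    bounds = np.linspace(0, len(common), n_jk + 1).astype(int)
    full = _wls(X, chi2, w)
    deletes = np.empty((n_jk, X.shape[1]))
    for b in range(n_jk):
        keep = np.ones(len(common), dtype=bool)
        keep[bounds[b] : bounds[b + 1]] = False
        deletes[b] = _wls(X[keep], chi2[keep], w[keep])
    mean_d = deletes.mean(axis=0)
    se = np.sqrt((n_jk - 1) / n_jk * ((deletes - mean_d) ** 2).sum(axis=0))

    tau = pd.Series(full[1:], index=cats)
    tau_se = pd.Series(se[1:], index=cats)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = pd.Series(stats.norm.sf(tau / tau_se), index=cats)
    return LdscFit(
        tau=tau,
        se=tau_se,
        p=p,
        intercept=float(full[0]),
        intercept_se=float(se[0]),
        n_snps=len(common),
        n_blocks_jackknife=n_jk,
    )


def _near_duplicate(a: np.ndarray, b: np.ndarray, thresh: float = 0.95) -> bool:
    inter = float(np.minimum(a, b).sum())
    union = float(np.maximum(a, b).sum())
    return union > 0 and inter / union > thresh


def conditional_fit(
    study: GwasStudy,
    target: str,
    annotation: Annotation,
    panel: LDPanel,
    control_sets: list[str],
    n_jackknife_blocks: int = 200,
    alpha: float = 0.05,
    scores: pd.DataFrame | None = None,
) -> LdscFit:
    """Target coefficient test with control categories in the design.

    The returned fit records the verdict on the target under the controls:
    "distinct" when the conditional coefficient p < alpha,
    "indistinguishable" otherwise. Near-duplicate target/control
    categories (membership Jaccard > 0.95) are rejected.
    """
    if target in control_sets:
        raise ValueError("target category cannot also be a control")
    cats = [BASELINE, target] + list(control_sets)
    missing = [c for c in cats if c not in annotation.df.columns]
    if missing:
        raise ValueError(f"categories absent from annotation: {missing}")
    tvec = annotation.df[target].to_numpy(dtype=float)
    for c in control_sets:
        if _near_duplicate(tvec, annotation.df[c].to_numpy(dtype=float)):
            raise ValueError(
                f"control category {c!r} nearly duplicates target {target!r}"
            )
    if scores is None:
        scores = ld_scores(Annotation(annotation.df[cats].copy()), panel)
    else:
        scores = scores[cats]
    fit = fit_stratified(study, scores, n_jackknife_blocks)
    fit.target = target
    fit.verdict = "distinct" if fit.p[target] < alpha else "indistinguishable"
    return fit
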