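"""LD-aware gene statistics and the one-sided competitive gene-set test.

Gene statistic: the mean chi-square of a gene's SNP z-scores. Under the
null, z ~ MVN(0, R) within LD blocks, so the sum of squares is a weighted
chi-square mixture with weights the eigenvalues of the SNP correlation
matrix; the p-value uses a Satterthwaite scaled-chi-square approximation
matching the mixture's first two moments. The gene Z is the probit of
1 - p.

Competitive test: OLS of gene Z on an intercept, the set-membership
indicator, log SNP count, log gene length, and optional conditioning-set
indicators; the one-sided p asks whether set genes carry more association
than non-set genes. With no covariates it reduces exactly to a pooled
-variance two-sample t-test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GeneAnnotation, GwasStudy, LDPanel

log = logging.getLogger(__name__)


def map_snps_to_genes(
    sumstats: pd.DataFrame | GwasStudy,
    genes: GeneAnnotation,
    window_kb: float = 10.0,
) -> dict[str, list[str]]:
    """Assign SNPs to every gene whose windowed interval contains them.

    Gene intervals are 0-based half-open; SNP positions are 1-based. A SNP
    at 1-based position ``pos`` falls in a gene iff
    ``start - w <= pos - 1 < end + w``. Multi-assignment is allowed.
    """
    df = sumstats.df if isinstance(sumstats, GwasStudy) else sumstats
    w = int(window_kb * 1000)
    out: dict[str, list[str]] = {}
    by_chrom = {c: sub for c, sub in df.groupby("CHR")}
    for row in genes.df.itertuples(index=False):
        sub = by_chrom.get(row.CHR)
        if sub is None:
            continue
        pos0 = sub["BP"].to_numpy() - 1
        hit = (pos0 >= row.start - w) & (pos0 < row.end + w)
        if hit.any():
            out[row.gene] = sub.loc[hit, "SNP"].tolist()
    return out


def _satterthwaite_sf(q: float, lam: np.ndarray) -> float:
    """Two-moment scaled-chi-square tail approximation for sum(lam_i X_i),
    X_i ~ chi2(1)."""
    s1, s2 = lam.sum(), float(lam @ lam)
    if s2 == 0:
        raise ValueError("degenerate correlation matrix")
    return float(stats.chi2.sf(q / (s2 / s1), s1 * s1 / s2))


def _imhof_sf(q: float, lam: np.ndarray) -> float:
    """Exact tail of a weighted chi-square mixture by Imhof's inversion:
    P(Q > q) = 1/2 + (1/pi) * int_0^inf sin(theta(u)) / (u * rho(u)) du."""
    import warnings

    from scipy import integrate

    lam = lam[lam > 1e-12]

    def integrand(u):
        theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * q * u
        rho = np.exp(0.25 * np.sum(np.log1p((lam * u) ** 2)))
        return np.sin(theta) / (u * rho)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, _ = integrate.quad(integrand, 0.0, np.inf, limit=500)
    return 0.5 + val / np.pi


def mixture_sf(q: float, lam: np.ndarray) -> float:
    """Upper tail of sum(lam_i chi2_1). Exact (Imhof) inside the range
    where the oscillatory integral is numerically trustworthy, with the
    two-moment approximation as tail/fallback."""
    lam = np.asarray(lam, dtype=float)
    pos = lam[lam > 1e-12 * max(lam.max(), 1.0)]
    if len(pos) == 0:
        raise ValueError("degenerate correlation matrix")
    if np.ptp(pos) <= 1e-10 * pos.max():
        # equal eigenvalues: the mixture is an exact scaled chi-square
        return float(stats.chi2.sf(q / pos.max(), len(pos)))
    p_approx = _satterthwaite_sf(q, lam)
    if p_approx < 1e-8 or p_approx > 1.0 - 1e-10:
        return p_approx
    try:
        p = _imhof_sf(q, lam)
    except Exception:
        return p_approx
    if not 0.0 < p < 1.0 or (p_approx > 1e-6 and not (0.1 < p / p_approx < 10.0)):
        return p_approx
    return p


def gene_statistic(z: np.ndarray, R: np.ndarray) -> tuple[float, float]:
    """Mean-chi-square gene statistic and its eigenvalue-mixture p-value.

    Under the null z ~ MVN(0, R), so sum(z^2) is distributed as the
    eigenvalue-weighted chi-square mixture of R; the tail probability is
    computed by Imhof inversion (two-moment approximation in the extreme
    tails). Invariant to SNP order and to sign flips of z.
    """
    z = np.asarray(z, dtype=float)
    m = len(z)
    if m == 0:
        raise ValueError("gene has no SNPs")
    if R.shape != (m, m):
        raise ValueError("correlation matrix does not match z length")
    q = float(z @ z)  # m * mean chi-square
    lam = np.clip(np.linalg.eigvalsh(R), 0.0, None)
    p = mixture_sf(q, lam)
    return q / m, p


@dataclass
class GeneStats:
    """Per-gene LD-adjusted statistics and regression covariates."""

    df: pd.DataFrame  # columns: gene, n_snps, length, stat, p, Z

    @property
    def genes(self) -> pd.Index:
        return pd.Index(self.df["gene"])


MIN_GENE_P = 1e-300


def compute_gene_stats(
    study: GwasStudy,
    panel: LDPanel,
    genes: GeneAnnotation,
    window_kb: float = 10.0,
    snp_map: dict[str, list[str]] | None = None,
) -> GeneStats:
    """Gene statistics for every annotated gene with panel-covered SNPs.

    Genes whose SNPs are absent from the panel or sumstats are skipped
    (logged). Gene Z = probit of (1 - p), clipped away from 0/1.
    """
    snp_map = snp_map or map_snps_to_genes(study, genes, window_kb)
    zmap = study.zmap()
    lengths = genes.lengths()
    rows = []
    n_skipped = 0
    for gene, snps in snp_map.items():
        snps = [s for s in snps if s in zmap.index and panel.locate(s) is not None]
        if not snps:
            n_skipped += 1
            continue
        z = zmap[snps].to_numpy()
        R = panel.submatrix(snps)
        stat, p = gene_statistic(z, R)
        rows.append((gene, len(snps), int(lengths[gene]), stat, p))
    if n_skipped:
        log.info("skipped %d genes with no usable SNPs", n_skipped)
    df = pd.DataFrame(rows, columns=["gene", "n_snps", "length", "stat", "p"])
    p = np.clip(df["p"].to_numpy(), MIN_GENE_P, 1 - 1e-16)
    df["Z"] = stats.norm.isf(p)
    return GeneStats(df)


@dataclass
class AssocRecord:
    """One gene-set association: effect, one-sided p, correction, context."""

    trait: str
    set_name: str
    beta: float
    se: float
    stat: float
    p: float
    q: float
    n_set: int
    method: str = "magma-like"
    conditioning: str = ""

    def to_dict(self) -> dict:
        return {
            "trait": self.trait,
            "set": self.set_name,
            "beta": self.beta,
            "se": self.se,
            "stat": self.stat,
            "p": self.p,
            "q": self.q,
            "n_set": self.n_set,
            "method": self.method,
            "conditioning": self.conditioning,
        }


def competitive_set_test(
    gene_stats: GeneStats,
    gene_set: list[str] | set[str],
    covariates: bool = True,
    condition_sets: dict[str, list[str]] | None = None,
    set_name: str = "set",
    trait: str = "trait",
) -> AssocRecord:
    """One-sided competitive test: do set genes have larger gene Z?

    OLS of gene Z on intercept + set indicator (+ log n_snps + log length
    when ``covariates`` + one indicator per conditioning set); p is the
    upper-tail t probability for the set coefficient.
    """
    df = gene_stats.df
    genes = df["gene"].to_numpy()
    s = np.isin(genes, list(gene_set)).astype(float)
    n_set = int(s.sum())
    if n_set < 2 or (len(s) - n_set) < 2:
        raise ValueError(
            f"set {set_name!r}: need >= 2 genes inside and outside the set "
            f"among tested genes (got {n_set} of {len(s)})"
        )
    cols = [np.ones(len(s)), s]
    names = ["intercept", "set"]
    if covariates:
        cols += [np.log(df["n_snps"].to_numpy()), np.log(df["length"].to_numpy())]
        names += ["log_n_snps", "log_length"]
    for cname, cset in (condition_sets or {}).items():
        ind = np.isin(genes, list(cset)).astype(float)
        if np.array_equal(ind, s):
            raise ValueError(
                f"conditioning set {cname!r} is identical to the tested set "
                f"{set_name!r}"
            )
        for prev, pn in zip(cols[2 + (2 if covariates else 0):], names[2 + (2 if covariates else 0):]):
            if np.array_equal(ind, prev):
                raise ValueError(
                    f"conditioning sets {cname!r} and {pn!r} are identical"
                )
        cols.append(ind)
        names.append(cname)
    X = np.column_stack(cols)
    y = df["Z"].to_numpy()

    XtX = X.T @ X
    if np.linalg.matrix_rank(XtX) < X.shape[1]:
        raise ValueError(f"collinear design for set {set_name!r} ({names})")
    coef = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ coef
    dof = len(y) - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(XtX)
    beta, se = float(coef[1]), float(np.sqrt(cov[1, 1]))
    t = beta / se
    p = float(stats.t.sf(t, dof))
    cond = ",".join((condition_sets or {}).keys())
    return AssocRecord(
        trait=trait, set_name=set_name, beta=beta, se=se, stat=t, p=p, q=np.nan,
        n_set=n_set, method="magma-like", conditioning=cond,
    )


def _tier(p: float, q: float) -> str:
    """Significance tier: '**' for corrected q < 0.05, '*' for nominal
    p < 0.05, '' otherwise."""
    if q < 0.05:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def celltype_scan(
    gene_stats: GeneStats,
    cell_type_sets: dict[str, list[str]],
    trait: str = "trait",
    condition_sets: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Competitive test per cell type, Bonferroni-corrected over types.

    Returns a frame with per-type beta/SE/t/p, q = min(1, p * n_types),
    and the */** significance tier.
    """
    if not cell_type_sets:
        raise ValueError("no cell-type gene sets supplied")
    recs = [
        competitive_set_test(
            gene_stats, gs, set_name=ct, trait=trait, condition_sets=condition_sets
        )
        for ct, gs in sorted(cell_type_sets.items())
    ]
    out = pd.DataFrame([r.to_dict() for r in recs])
    out["q"] = np.minimum(1.0, out["p"] * len(recs))
    out["tier"] = [_tier(p, q) for p, q in zip(out["p"], out["q"])]
    return out


def module_scan(
    gene_stats: GeneStats,
    modules: dict[str, list[str]],
    trait: str = "trait",
    condition_sets: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Competitive test per PPI module, Bonferroni over all modules tested.

    Modules are tested on their intersection with the annotated genes; a
    module covered < 50% triggers a warning, one with no usable genes is
    skipped with a warning.
    """
    tested = set(gene_stats.genes)
    recs = []
    for mid, mgenes in sorted(modules.items()):
        inter = [g for g in mgenes if g in tested]
        if len(inter) < 2:
            warnings.warn(f"module {mid} disjoint from annotated genes; skipped")
            continue
        if len(inter) < 0.5 * len(mgenes):
            warnings.warn(
                f"module {mid}: only {len(inter)}/{len(mgenes)} genes covered"
            )
        recs.append(
            competitive_set_test(
                gene_stats, inter, set_name=mid, trait=trait,
                condition_sets=condition_sets,
            )
        )
    out = pd.DataFrame([r.to_dict() for r in recs])
    if len(out):
        out["method"] = "magma-like"
        out["q"] = np.minimum(1.0, out["p"] * len(out))
        out["tier"] = [_tier(p, q) for p, q in zip(out["p"], out["q"])]
    return out
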