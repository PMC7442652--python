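"""Cross-disorder conditioning of GWAS summary statistics.

To ask whether two disorders act on a cell type through shared or
distinct loci, one disorder's summary statistics are adjusted for the
genetic effects of the other before re-running the cell-type association.
The conditioning effect b_xy is estimated as the median, over
genome-wide-significant instrument SNPs of the conditioning trait (pruned
to one per LD block), of the ratio of standardized effects b = z / sqrt(N),
with a delete-one-instrument jackknife SE. Per SNP the adjusted effect is
b1 - b_xy * b2 with SE inflated by sqrt(1 + b_xy^2) under the
independent-sample approximation. This is a deliberately lean stand-in
for full multi-trait conditional-and-joint machinery: it preserves the
inferential contract (remove trait-2-mediated signal) without LD-aware
joint effect estimation.

The cross-disorder matrix re-runs the stratified-LDSC cell-type test on
the conditioned statistics for every eligible (cell type, disorder pair),
with BH-FDR over tested entries; pairs are eligible only where both
disorders associate (at least suggestively) with the cell type in the
marginal scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datatypes import GwasStudy, LDPanel
from .ldsc import Annotation, fit_stratified, ld_scores

GWS_THRESHOLD = 5e-8


@dataclass
class TraitPair:
    """A primary trait, a conditioning trait, and the estimated b_xy."""

    primary: GwasStudy
    conditioning: GwasStudy
    b_xy: float
    se: float
    instruments: list[str]


def _standardized_effects(study: GwasStudy) -> pd.Series:
    return pd.Series(study.z / np.sqrt(study.n), index=study.df["SNP"].to_numpy())


def select_instruments(
    study: GwasStudy, panel: LDPanel, p_threshold: float = GWS_THRESHOLD
) -> list[str]:
    """Genome-wide-significant SNPs pruned to the top SNP per LD block."""
    df = study.df
    sig = df.loc[study.p < p_threshold, ["SNP", "Z"]].copy()
    best: dict[int, tuple[str, float]] = {}
    for snp, z in zip(sig["SNP"], sig["Z"]):
        b = panel.block_of(snp)
        if b is None:
            continue
        if b not in best or abs(z) > best[b][1]:
            best[b] = (snp, abs(z))
    return [snp for snp, _ in best.values()]


def estimate_bxy(
    primary: GwasStudy,
    conditioning: GwasStudy,
    panel: LDPanel,
    p_threshold: float = GWS_THRESHOLD,
    min_instruments: int = 5,
) -> TraitPair:
    """Median-ratio estimate of the conditioning trait's effect on the
    primary trait, with delete-one-instrument jackknife SE."""
    instruments = select_instruments(conditioning, panel, p_threshold)
    if len(instruments) < min_instruments:
        raise ValueError(
            f"only {len(instruments)} instruments at p < {p_threshold:g}; "
            "relax p_threshold to proceed"
        )
    b1 = _standardized_effects(primary)[instruments].to_numpy()
    b2 = _standardized_effects(conditioning)[instruments].to_numpy()
    ratios = b1 / b2
    bxy = float(np.median(ratios))
    n = len(ratios)
    jack = np.array(
        [np.median(np.delete(ratios, i)) for i in range(n)]
    )
    se = float(np.sqrt((n - 1) / n * ((jack - jack.mean()) ** 2).sum()))
    return TraitPair(
        primary=primary, conditioning=conditioning, b_xy=bxy, se=se,
        instruments=instruments,
    )


def condition_sumstats(pair: TraitPair) -> GwasStudy:
    """Adjust the primary trait's statistics for the conditioning trait.

    b1_adj = b1 - b_xy * b2 on the standardized scale; the SE inflation
    sqrt(1 + b_xy^2) assumes non-overlapping GWAS samples. Identity when
    b_xy = 0. SNPs are matched on id after allele harmonization; SNPs
    whose alleles cannot be reconciled by swapping are dropped.
    """
    p1 = pair.primary.df.set_index("SNP")
    p2 = pair.conditioning.df.set_index("SNP")
    common = p1.index.intersection(p2.index)
    a1 = p1.loc[common]
    a2 = p2.loc[common]
    same = (a1["A1"] == a2["A1"]) & (a1["A2"] == a2["A2"])
    flipped = (a1["A1"] == a2["A2"]) & (a1["A2"] == a2["A1"])
    keep = same | flipped
    sign = np.where(flipped, -1.0, 1.0)[keep.to_numpy()]
    a1, a2 = a1[keep.to_numpy()], a2[keep.to_numpy()]

    b1 = a1["Z"].to_numpy() / np.sqrt(a1["N"].to_numpy(dtype=float))
    b2 = sign * a2["Z"].to_numpy() / np.sqrt(a2["N"].to_numpy(dtype=float))
    b_adj = b1 - pair.b_xy * b2
    z_adj = b_adj * np.sqrt(a1["N"].to_numpy(dtype=float)) / np.sqrt(
        1.0 + pair.b_xy**2
    )
    out = a1.reset_index()
    out["Z"] = z_adj
    return GwasStudy(
        out,
        trait=f"{pair.primary.trait}|{pair.conditioning.trait}",
    )


def cross_disorder_matrix(
    studies: dict[str, GwasStudy],
    marginal: pd.DataFrame,
    annotation: Annotation,
    panel: LDPanel,
    eligibility_p: float = 0.05,
    scores: pd.DataFrame | None = None,
    min_instruments: int = 5,
) -> pd.DataFrame:
    """Conditional (cell type, disorder1 | disorder2) association matrix.

    ``marginal`` must hold columns ``trait``, ``set`` (cell type) and
    ``p`` from the marginal cell-type scan; a (cell type, d1, d2) entry is
    evaluated only when both disorders reach p < ``eligibility_p`` on that
    cell type. Evaluated entries carry the stratified-LDSC coefficient p
    of the cell type on d1's statistics conditioned on d2, and BH-FDR q
    over evaluated entries; others are flagged not evaluated.
    """
    if scores is None:
        scores = ld_scores(annotation, panel)
    cell_types = [c for c in annotation.df.columns if c != "baseline"]
    sig = {
        (r.trait, r.set): r.p < eligibility_p for r in marginal.itertuples()
    }
    rows = []
    traits = sorted(studies)
    for ct in cell_types:
        for d1 in traits:
            for d2 in traits:
                if d1 == d2:
                    continue
                eligible = sig.get((d1, ct), False) and sig.get((d2, ct), False)
                if not eligible:
                    rows.append((ct, d1, d2, np.nan, np.nan, False))
                    continue
                pair = estimate_bxy(
                    studies[d1], studies[d2], panel, min_instruments=min_instruments
                )
                adj = condition_sumstats(pair)
                fit = fit_stratified(adj, scores[["baseline", ct]])
                rows.append((ct, d1, d2, float(fit.p[ct]), np.nan, True))
    out = pd.DataFrame(
        rows, columns=["cell_type", "disease1", "disease2", "p", "q", "evaluated"]
    )
    mask = out["evaluated"].to_numpy()
    if mask.any():
        out.loc[mask, "q"] = sm.stats.multipletests(
            out.loc[mask, "p"], method="fdr_bh"
        )[1]
    return out
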