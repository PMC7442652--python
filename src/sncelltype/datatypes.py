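"""Shared containers for GWAS summary statistics and LD reference panels.

Summary statistics live in a pandas DataFrame with the columns
``SNP CHR BP A1 A2 Z N``; the LD reference is a list of disjoint SNP blocks,
each carrying its SNP ids and the within-block correlation matrix.
Cross-block correlation is treated as zero throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

SUMSTAT_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "Z", "N"]


def _normalize_chrom(c) -> str:
    """Map 'chr1'/'Chr1'/1 → '1' so annotation dialects interoperate."""
    s = str(c)
    if s.lower().startswith("chr"):
        s = s[3:]
    return s


@dataclass
class GwasStudy:
    """Harmonized per-SNP summary statistics for one trait.

    ``df`` columns: SNP (id), CHR, BP (1-based), A1/A2 (effect/other allele),
    Z (signed score on the standardized scale), N (GWAS sample size).
    """

    df: pd.DataFrame
    trait: str = "trait"

    def __post_init__(self) -> None:
        missing = [c for c in SUMSTAT_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"sumstats missing columns: {missing}")
        self.df = self.df.copy()
        self.df["CHR"] = self.df["CHR"].map(_normalize_chrom)
        if "P" in self.df.columns:
            p = np.asarray(self.df["P"], dtype=float)
            z = np.asarray(self.df["Z"], dtype=float)
            bad = ~np.isclose(2.0 * stats.norm.sf(np.abs(z)), p, atol=1e-6)
            if bad.any():
                raise ValueError(
                    f"{int(bad.sum())} SNPs have inconsistent Z and P columns"
                )

    @property
    def p(self) -> np.ndarray:
        """Two-sided normal p-values implied by Z."""
        return 2.0 * stats.norm.sf(np.abs(self.z))

    @property
    def z(self) -> np.ndarray:
        return np.asarray(self.df["Z"], dtype=float)

    @property
    def n(self) -> np.ndarray:
        return np.asarray(self.df["N"], dtype=float)

    @property
    def snps(self) -> pd.Index:
        return pd.Index(self.df["SNP"])

    def zmap(self) -> pd.Series:
        return pd.Series(self.z, index=self.df["SNP"].to_numpy())

    def with_z(self, z: np.ndarray, trait: str | None = None) -> "GwasStudy":
        df = self.df.copy()
        df["Z"] = np.asarray(z, dtype=float)
        df.drop(columns=[c for c in ("P",) if c in df.columns], inplace=True)
        return GwasStudy(df, trait=trait or self.trait)


@dataclass
class LDBlock:
    """One LD block: SNP ids in order and their correlation matrix."""

    snps: np.ndarray
    R: np.ndarray

    def __post_init__(self) -> None:
        self.snps = np.asarray(self.snps, dtype=object)
        self.R = np.asarray(self.R, dtype=float)
        m = len(self.snps)
        if self.R.shape != (m, m):
            raise ValueError("block correlation matrix shape mismatch")
        if not np.allclose(self.R, self.R.T, atol=1e-10):
            raise ValueError("block correlation matrix not symmetric")
        if not np.allclose(np.diag(self.R), 1.0, atol=1e-8):
            raise ValueError("block correlation matrix diagonal must be 1")


@dataclass
class LDPanel:
    """Ordered disjoint LD blocks covering the panel's SNPs."""

    blocks: list[LDBlock]
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {}
        for bi, b in enumerate(self.blocks):
            for si, s in enumerate(b.snps):
                if s in self._index:
                    raise ValueError(f"SNP {s} appears in more than one block")
                self._index[s] = (bi, si)

    @property
    def snps(self) -> list:
        return [s for b in self.blocks for s in b.snps]

    def locate(self, snp) -> tuple[int, int] | None:
        return self._index.get(snp)

    def block_of(self, snp) -> int | None:
        loc = self._index.get(snp)
        return None if loc is None else loc[0]

    def submatrix(self, snps: Sequence) -> np.ndarray:
        """Block-diagonal correlation matrix for the given SNPs.

        SNPs from different blocks are uncorrelated; SNPs absent from the
        panel are rejected.
        """
        locs = []
        for s in snps:
            loc = self.locate(s)
            if loc is None:
                raise KeyError(f"SNP {s} not in LD panel")
            locs.append(loc)
        m = len(locs)
        R = np.zeros((m, m))
        for i, (bi, si) in enumerate(locs):
            for j, (bj, sj) in enumerate(locs):
                if bi == bj:
                    R[i, j] = self.blocks[bi].R[si, sj]
        return R


@dataclass
class GeneAnnotation:
    """Gene locations, 0-based half-open internally.

    ``df`` columns: gene, CHR, start, end (start < end, 0-based half-open).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        need = ["gene", "CHR", "start", "end"]
        missing = [c for c in need if c not in self.df.columns]
        if missing:
            raise ValueError(f"gene annotation missing columns: {missing}")
        self.df = self.df.copy()
        self.df["CHR"] = self.df["CHR"].map(_normalize_chrom)
        if (self.df["start"] >= self.df["end"]).any():
            raise ValueError("gene annotation has start >= end")

    @property
    def genes(self) -> pd.Index:
        return pd.Index(self.df["gene"])

    def lengths(self) -> pd.Series:
        return pd.Series(
            (self.df["end"] - self.df["start"]).to_numpy(),
            index=self.df["gene"].to_numpy(),
        )
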