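"""Readers and writers for the package's on-disk formats.

10x-style MTX triplet directories, GWAS sumstats TSV, BED-like gene
annotation, GMT gene sets, PPI edge lists, and result tables with the
*/** significance-tier encoding. Readers reject malformed inputs loudly;
the only silent coercions are documented dialect normalizations
(chromosome names, 2- vs 3-column features files), which are logged.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import Mapping, Sequence

import anndata as ad
import igraph
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse, stats

from .datatypes import GeneAnnotation, GwasStudy, SUMSTAT_COLUMNS

log = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


class FormatError(ValueError):
    """Malformed input file."""


def _open_maybe_gz(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _find(dir_: Path, stems: Sequence[str]) -> Path:
    for stem in stems:
        for name in (stem, stem + ".gz"):
            p = dir_ / name
            if p.exists():
                return p
    raise FileNotFoundError(f"none of {stems} found in {dir_}")


def read_10x_mtx(directory: str | Path) -> ad.AnnData:
    """Read a 10x-dialect MTX triplet directory into cells x genes counts.

    Accepts plain or gzipped ``matrix.mtx``, ``features.tsv`` (or
    ``genes.tsv``; 2- or 3-column) and ``barcodes.tsv``. The matrix on
    disk is genes x cells, as written by Cell Ranger. Header dimensions
    are validated against the features/barcodes files and triplet extent.
    """
    directory = Path(directory)
    mtx_path = _find(directory, ["matrix.mtx"])
    feat_path = _find(directory, ["features.tsv", "genes.tsv"])
    bc_path = _find(directory, ["barcodes.tsv"])

    try:
        with _open_maybe_gz(mtx_path) as fh:
            M = spio.mmread(fh)
    except Exception as e:  # triplet entries outside header dims, bad header...
        raise FormatError(f"cannot parse {mtx_path}: {e}") from e
    M = sparse.csr_matrix(M.T)  # cells x genes

    feats = pd.read_csv(feat_path, sep="\t", header=None, dtype=str)
    if feats.shape[1] == 2:
        log.info("features file has 2 columns; feature type defaulted")
        feats[2] = "Gene Expression"
    elif feats.shape[1] < 2:
        raise FormatError(f"{feat_path}: expected >= 2 columns")
    barcodes = pd.read_csv(bc_path, sep="\t", header=None, dtype=str)[0]

    if M.shape != (len(barcodes), len(feats)):
        raise FormatError(
            f"matrix is {M.shape[1]} genes x {M.shape[0]} cells but features/"
            f"barcodes give {len(feats)} x {len(barcodes)}"
        )
    var = pd.DataFrame(
        {"gene_id": feats[0].to_numpy(), "feature_type": feats[2].to_numpy()},
        index=feats[1].to_numpy(),
    )
    var.index = ad.utils.make_index_unique(pd.Index(var.index))
    symbols = var.index.to_series()
    var["mito"] = symbols.str.upper().str.startswith("MT-").to_numpy()
    var["ribo"] = symbols.str.upper().str.match(r"^RP[SL]").to_numpy()
    adata = ad.AnnData(
        X=M, obs=pd.DataFrame(index=barcodes.to_numpy()), var=var
    )
    return adata


def write_10x_mtx(adata: ad.AnnData, directory: str | Path) -> None:
    """Write a plain-text 10x triplet (matrix.mtx, features.tsv, barcodes.tsv)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    X = sparse.coo_matrix(adata.X.T.astype(np.int64))  # genes x cells on disk
    spio.mmwrite(str(directory / "matrix.mtx"), X, field="integer")
    feats = pd.DataFrame(
        {
            0: adata.var.get("gene_id", pd.Series(adata.var_names, index=adata.var_names)),
            1: adata.var_names,
            2: adata.var.get("feature_type", "Gene Expression"),
        }
    )
    feats.to_csv(directory / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(
        directory / "barcodes.tsv", sep="\t", header=False, index=False
    )


def read_sumstats(path: str | Path, trait: str | None = None) -> GwasStudy:
    """Read a sumstats TSV (SNP CHR BP A1 A2 Z N; P accepted for Z).

    When Z is absent, |Z| is recovered from the two-sided P and signed by
    a BETA or OR column if present (positive otherwise, with a warning).
    Duplicate SNP ids keep the first occurrence (logged).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = ["SNP", "CHR", "BP", "A1", "A2", "N"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    if "Z" not in df.columns:
        if "P" not in df.columns:
            raise FormatError(f"{path}: need a Z or P column")
        absz = stats.norm.isf(np.clip(df["P"].to_numpy(dtype=float), 1e-300, 1) / 2)
        if "BETA" in df.columns:
            sign = np.sign(df["BETA"].to_numpy(dtype=float))
        elif "OR" in df.columns:
            sign = np.sign(np.log(df["OR"].to_numpy(dtype=float)))
        else:
            log.warning("%s: no effect column; Z signs set positive", path)
            sign = 1.0
        df["Z"] = absz * np.where(sign == 0, 1.0, sign)
        df = df.drop(columns=["P"])
    n_dup = int(df.duplicated("SNP").sum())
    if n_dup:
        log.info("%s: dropped %d duplicate SNP ids (first kept)", path, n_dup)
        df = df.drop_duplicates("SNP", keep="first")
    return GwasStudy(df[SUMSTAT_COLUMNS + [c for c in df.columns if c not in SUMSTAT_COLUMNS]],
                     trait=trait or path.stem)


def write_sumstats(study: GwasStudy, path: str | Path) -> None:
    study.df[SUMSTAT_COLUMNS].to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_gene_annotation(
    path: str | Path, dialect: str = "bed"
) -> GeneAnnotation:
    """Read a BED-like gene TSV: chrom, start, end, gene.

    ``dialect='bed'`` treats coordinates as 0-based half-open (native);
    ``dialect='onebased'`` as 1-based inclusive, converted internally. A
    strand column, if present, is preserved but ignored by SNP windows.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 4:
        raise FormatError(f"{path}: expected >= 4 columns (chrom start end gene)")
    cols = ["CHR", "start", "end", "gene"] + [
        f"extra{i}" for i in range(df.shape[1] - 4)
    ]
    df.columns = cols
    if df.shape[1] > 4 and df.iloc[:, 4].isin(["+", "-"]).all():
        df = df.rename(columns={"extra0": "strand"})
    if dialect == "onebased":
        df["start"] = df["start"] - 1
    elif dialect != "bed":
        raise ValueError(f"unknown coordinate dialect {dialect!r}")
    return GeneAnnotation(df[["gene", "CHR", "start", "end"]
                             + [c for c in df.columns if c == "strand"]])


def write_gene_annotation(genes: GeneAnnotation, path: str | Path) -> None:
    out = genes.df[["CHR", "start", "end", "gene"]]
    out.to_csv(path, sep="\t", header=False, index=False)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file: set name, description, then member genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: GMT rows need >= 3 fields")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_edge_list(path: str | Path) -> igraph.Graph:
    """Read a PPI edge list TSV (geneA, geneB[, weight]) into a simple graph.

    Self-loops and duplicate edges are removed; a weight column is parsed
    but ignored by module detection (logged).
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected >= 2 columns")
    if df.shape[1] >= 3:
        log.info("%s: weight column present; ignored by module detection", path)
    nodes = sorted(set(df[0]) | set(df[1]))
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[a], index[b]) for a, b in zip(df[0], df[1]) if a != b]
    g = igraph.Graph(n=len(nodes), edges=edges, directed=False)
    g.vs["name"] = nodes
    g.simplify()
    return g


def write_edge_list(g: igraph.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in g.es:
            fh.write(f"{g.vs[e.source]['name']}\t{g.vs[e.target]['name']}\n")


def significance_tier(p: float, q: float) -> str:
    """Fig-2-style tiers: '**' when the corrected q < 0.05, '*' when only
    the nominal p < 0.05."""
    if q < 0.05:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def write_results(records: pd.DataFrame, path: str | Path,
                  float_format: str = FLOAT_FORMAT) -> None:
    """Write an association result table with stable column order, fixed
    float precision, and the */** tier column when p and q are present."""
    df = records.copy()
    if "p" in df.columns and "q" in df.columns and "tier" not in df.columns:
        df["tier"] = [significance_tier(p, q) for p, q in zip(df["p"], df["q"])]
    lead = [c for c in ["trait", "set", "cell_type", "module", "disease1",
                        "disease2", "term"] if c in df.columns]
    rest = [c for c in df.columns if c not in lead]
    df[lead + rest].to_csv(path, sep="\t", index=False, float_format=float_format)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
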