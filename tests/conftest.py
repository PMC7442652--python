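import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from sncelltype.atlas import normalize_and_regress, qc_filter
from sncelltype.geneassoc import compute_gene_stats
from sncelltype.pipeline import RunConfig, run_pipeline
from sncelltype.atlas import QcThresholds
from sncelltype.presets import null_gwas_spec
from sncelltype.synth import AtlasSimSpec, simulate_atlas, simulate_gwas


def make_adata(counts, mito=None, ribo=None, sample=None, **obs_cols):
    """Small AnnData from a dense cells x genes array."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    var = pd.DataFrame(index=[f"g{j}" for j in range(n_genes)])
    var["mito"] = np.zeros(n_genes, bool) if mito is None else np.asarray(mito, bool)
    var["ribo"] = np.zeros(n_genes, bool) if ribo is None else np.asarray(ribo, bool)
    obs = pd.DataFrame(index=[f"cell{i}" for i in range(n_cells)])
    obs["sample"] = "s1" if sample is None else sample
    for k, v in obs_cols.items():
        obs[k] = v
    return ad.AnnData(X=sparse.csr_matrix(counts.astype(np.int64)), obs=obs, var=var)


@pytest.fixture(scope="session")
def small_atlas():
    """Three planted types (100 cells each), fold-8 markers, QC'd and
    normalized."""
    spec = AtlasSimSpec(
        n_cell_types=3,
        cells_per_type=[100, 100, 100],
        n_genes=500,
        markers_per_type=20,
        marker_fold_change=8.0,
        seed=5,
    )
    adata = simulate_atlas(spec)
    adata, _ = qc_filter(adata, QcThresholds(min_genes_per_cell=150))
    return normalize_and_regress(adata)


@pytest.fixture(scope="session")
def null_sim():
    """Null GWAS: 500 blocks x 40 SNPs, no planted effects."""
    return simulate_gwas(null_gwas_spec(seed=11))


@pytest.fixture(scope="session")
def null_gene_stats(null_sim):
    return compute_gene_stats(null_sim.study, null_sim.panel, null_sim.genes)


@pytest.fixture(scope="session")
def pipeline_dir(tmp_path_factory):
    """One full pipeline run on the default synthetic study, shared by the
    pipeline and acceptance tests."""
    out = tmp_path_factory.mktemp("pipe") / "run"
    cfg = RunConfig(out_dir=str(out), seed=3, log_level="WARNING")
    run_pipeline(cfg)
    return out
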