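# sncelltype

Mapping the common genetic risk of brain disorders onto cell types
defined by single-nuclei RNA-seq — and deciding whether two associations
reflect the same loci or distinct ones.

The scientific setting is a region like the human substantia nigra (SN):
a droplet snRNA-seq atlas dominated by glia (~95%, mostly
oligodendrocytes) with small neuronal populations such as dopaminergic
(DaN) and GABAergic neurons. Given such an atlas and GWAS summary
statistics for a disorder, the package asks *which cell type's specific
genes carry the disorder's risk*, and then decomposes overlapping
signals: is a disorder's DaN association distinct from its
oligodendrocyte association? Do two disorders that hit the same cell
type act through shared or separate loci?

The package is a library (plus `examples/` scripts); every stage is
exercised end to end on synthetic data with planted ground truth, so the
whole chain is testable without restricted-access GWAS or sequencing
data.

## The pipeline

1. **Atlas processing** (`atlas`): QC (genes detected in ≥3 nuclei;
   nuclei filtered on detected genes, per-sample UMI caps,
   mitochondrial/ribosomal fraction ≤ 5%), depth normalization + log1p,
   per-gene OLS residualization on technical covariates, HVG selection,
   PCA, shared-nearest-neighbour graph with Jaccard weights, Louvain
   (multi-level modularity) clustering at resolution 0.4–0.8, clusters
   < 30 cells dropped.
2. **Markers & specificity** (`markers`): per-gene negative-binomial
   regression with log-depth offset and likelihood-ratio test (reported
   markers have logFC ≥ 0.25 and detection ≥ 25%; BH-FDR over the gene
   panel); specificity score
   `s(g,c) = mean_c(g) / Σ_c' mean_c'(g)` with top-decile gene sets per
   cell type; glial-proportion homogenization between regions by seeded
   downsampling.
3. **Association engine 1 — competitive gene-set test** (`geneassoc`):
   per-gene statistic = mean χ² of the gene's SNP z-scores; the null is
   the eigenvalue-weighted χ² mixture of the SNP correlation matrix,
   evaluated exactly by Imhof inversion; gene Z = Φ⁻¹(1 − p); then OLS
   of gene Z on the set indicator plus log SNP-count and log gene-length
   covariates, one-sided p for the set coefficient, Bonferroni over cell
   types.
4. **Association engine 2 — stratified LD-score regression** (`ldsc`):
   gene-set SNP annotations (±100 kb), partitioned LD scores
   `ℓ(j,c) = Σ_{k∈c} r²_jk`, weighted regression of per-SNP χ² on
   `N·ℓ(j,c)` with free intercept, delete-one-block jackknife SEs,
   one-sided coefficient p; conditional fits add control categories to
   decide "distinct" vs "indistinguishable".
5. **Cross-disorder conditioning** (`xtrait`): `b_xy` = median ratio of
   standardized effects over genome-wide-significant instruments of the
   conditioning trait (one per LD block); adjusted effects
   `b₁ − b_xy·b₂` with SE inflation `√(1+b_xy²)`; the cell-type scan is
   re-run on the adjusted statistics, giving a disorder × disorder ×
   cell-type matrix with BH-FDR q-values.
6. **PPI modules & GO** (`netmod`): cell-type-specific PPI subnetworks,
   Louvain modules (>30 genes kept), module-level competitive tests
   (Bonferroni over all modules), one-sided Fisher (hypergeometric) GO
   over-representation.
7. **Synthetic data** (`synth`/`presets`): NB count atlases with planted
   types and fold-change markers; GWAS z-scores per LD block from
   `MVN(R·√N·β, R)` with per-gene-set effect variances and optional
   shared effects between trait pairs; planted-partition PPI graphs;
   GO term maps with seedable terms.

## Worked example

```bash
python examples/03_celltype_risk_scan.py
```

simulates a 20,000-SNP trait (N = 50,000) with risk planted in a "DaN"
gene set and scans four cell-type sets with both engines:

```
competitive gene-set scan (Bonferroni q, ** = q < 0.05):
  set      beta            p            q tier
  DaN  3.490574 7.086201e-23 2.834481e-22   **
 GABA -0.444420 8.889027e-01 1.000000e+00
Micro -0.398367 8.631912e-01 1.000000e+00
  ODC  0.108869 3.825798e-01 1.000000e+00

stratified LD-score coefficients (one-sided p for tau > 0):
  DaN    tau =  2.21e-05  p = 6.59e-05
  ODC    tau = -1.70e-06  p = 7.69e-01
  ...
```

`beta` is the mean gene-Z excess of set genes over the rest after
covariate adjustment; `tau` is the per-SNP heritability contribution of
the set's annotation. Both engines single out the causal set — the
planted per-SNP effect variance was 4.2×10⁻⁵, and the LDSC coefficient
recovers that scale. The other examples cover clustering
(`01`), markers/specificity (`02`), conditional decomposition (`04`),
PPI modules with GO (`05`), and the full driver (`06`), whose
`run_pipeline(RunConfig(...))` writes every result table plus a manifest
of file hashes; the same seed reproduces every byte.

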