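# Methods

This note documents the models, estimators, defaults and design choices
behind `sncelltype`, and what the synthetic validation studies do and do
not establish about behaviour on real data.

## Atlas model and QC

Counts are modelled as negative binomial with mean/dispersion
parameterization, `Var = μ + μ²/θ`. The simulator draws gene baseline
means log-normally around `baseline_mean` (σ = 0.5), gives every cell a
log-normal depth factor (σ = 0.35), multiplies each planted marker's
mean by `marker_fold_change` in its home type, and inflates
mitochondrial-gene means 30-fold in a small fraction of "damaged" cells
so the mito-fraction QC rule has something to catch. Defaults follow the
substantia-nigra setting: one 95%-abundant oligodendrocyte type plus
five rare types of ~40 cells, fold-8 markers (25 per type), θ = 2,
baseline mean 1 UMI/gene/cell.

QC keeps genes detected in ≥ 3 nuclei, then cells by detected genes,
per-sample UMI cap, and mitochondrial/ribosomal fractions ≤ 5%. The
detected-gene floor is 500 for real >20,000-gene panels; the synthetic
presets use 300 against their ~1,000-gene panels (same ~detection
fraction). When no UMI cap is configured, each sample's 99.5th
percentile is used and recorded in the QC report; passing those resolved
caps back in makes re-filtering idempotent, which is also how the QC
invariance test is phrased. Cell metrics are computed on the input
matrix before the gene filter.

## Normalization, regression, clustering

Cells are scaled to 10,000 counts and log1p-transformed; each gene is
then residualized by OLS on standardized per-cell covariates (UMI count,
mito and ribo fraction; a `batch_key` adds sample dummies) and
centred/unit-scaled. Clustering selects the top `n_hvg` genes by
log-expression variance, takes `n_pcs` principal components (full SVD,
deterministic), builds a k-NN graph (k = `snn_k`, neighbour sets include
the cell), converts it to a shared-nearest-neighbour graph with Jaccard
edge weights pruned below 1/15, and optimizes multi-level modularity at
the configured resolution with a seeded RNG. Clusters under
`min_cluster_size` (30) are dropped and their cells flagged
`unassigned`.

Defaults: `n_hvg` equal to the synthetic panel size (1,000–1,200;
variance ranking only matters for real-sized panels, and rare-type
markers must survive it), `n_pcs` = 15, `snn_k` = 20, resolution 0.4.
The low end of the 0.4–0.8 resolution range is the default because
modularity optimization at higher resolutions tends to split large
homogeneous populations — exactly the failure mode a 95%-dominant glial
population invites; 0.4 recovers the planted partition across seeds
while still separating 40-cell types. Multi-sample alignment (CCA-style)
is not implemented: the synthetic data has no batch structure, and
`batch_key` residualization is the hook for data that does.

## Marker test and specificity

For each candidate gene (natural-log fold change ≥ 0.25 and in-cluster
detection ≥ 25%), a negative-binomial GLM of counts on an
in/out-cluster indicator with log-depth offset is compared to the
intercept-only model by likelihood ratio (χ²₁). The gene-wise dispersion
is a method-of-moments estimate from the group-means fit; a non-positive
estimate falls back to Poisson (flagged). BH-FDR uses the **full gene
panel** as the family, with prefiltered genes counted as
non-discoveries. This choice (the convention of the major droplet
toolkits, which correct over all genes in the dataset) matters: applying
BH only to the prefiltered subset loses FDR control, because effect-size
selection enriches the tested nulls for small p-values; with the
full-panel family, empirical FDR in the validation study is ~0.02 at
nominal 0.05 with power 1.0 for fold-8 markers at 100-vs-200 cells.

Specificity is the mean-expression proportion: depth-normalized linear
means per cell type, each gene's scores summing to 1; the top decile per
type forms that type's gene set. The metric and decile are exposed
because the field uses several close variants; both the continuous
scores and the discrete sets are emitted so either convention can drive
the engines. Homogenization downsamples the over-represented
glial/neuronal compartment of each region (uniformly, without
replacement, seeded) to the pooled glial fraction; because specificity
is a per-type mean, it is invariant in expectation to type abundance,
which is why association profiles correlate strongly before and after
(r ≈ 0.95 in the default study).

## Gene statistic and competitive test

A gene's statistic is the mean χ² of its SNP z-scores (SNPs assigned by
a ±10 kb window, 0-based half-open intervals, multi-assignment allowed;
genes spanning several LD blocks get a block-diagonal correlation
matrix). Under the null `z ~ MVN(0, R)`, so `Σz²` follows the
eigenvalue-weighted χ²₁ mixture of `R`. The tail probability is computed
by **exact Imhof inversion** (numerical integration of the
characteristic function), with the two-moment Satterthwaite
approximation used only in the extreme tails (p < 10⁻⁸) and as a
fallback; equal eigenvalues short-circuit to the exact scaled χ². The
two-moment approximation alone was measured at up to ~5% relative error
at moderate p, which is why the exact inversion is the default — the
validation study holds the gene p within 2% of a 10⁶-draw Monte-Carlo
oracle (and is in fact limited by the oracle's own noise). The oracle
comparison is restricted to p ∈ [0.01, 0.99], where a fixed-size Monte
Carlo estimate has small relative error.

The competitive test regresses gene Z = Φ⁻¹(1 − p) on an intercept, the
set indicator, log SNP count and log gene length (plus one indicator per
conditioning set); the one-sided p tests the set coefficient > 0. With
no covariates this is algebraically the pooled-variance two-sample
t-test. Cell-type scans Bonferroni-correct over cell types; module scans
over all modules tested in the run. Significance tiers follow the
convention: `*` nominal p < 0.05, `**` corrected q < 0.05.

The type-I validation (2,000 random null sets, rejection within 2
binomial SEs of 5%) is run on a light-LD null genome (r = 0.1, two genes
per block): gene-level statistics are then close to independent, which
is the regime the t-test's error-rate statement refers to. Under strong
within-block LD, genes sharing a block are correlated and random sets
show mild inflation (~0.5–1 point at α = 5%) — a property of competitive
tests generally, not of this implementation.

## Stratified LD-score regression

Gene sets become binary SNP annotations via a ±100 kb window (the
common cell-type-analysis convention; configurable). Partitioned LD
scores sum r² within blocks (cross-block r² = 0 by the panel's
construction). The fit is weighted least squares of per-SNP χ² on
`{N·ℓ(j,c)}` with a free intercept, weights `1/max(ℓ_baseline, 1)`;
coefficient SEs come from a delete-one-block jackknife over contiguous
SNP blocks (200 by default, shrunk automatically to ~1 block per 50
SNPs); the coefficient test is one-sided normal. The baseline is a
single all-SNPs category — the synthetic genome has no functional
annotation structure — and extra baseline categories can be supplied as
additional columns.

The recovery study plants a known per-SNP effect variance τ and uses a
0 kb annotation window so the category coincides exactly with the causal
gene bodies; the regression model then matches the generative model
(`E[χ²_j] = 1 + N·τ·ℓ(j,c)`) and τ̂ estimates τ directly (mean over 50
simulations within ~4%). With the 100 kb window the category dilutes and
τ̂ estimates an averaged causal density instead — expected behaviour,
not error.

Conditional fits add control categories to the design; the target's
coefficient p under controls is read as the verdict, "distinct"
(p < 0.05) vs "indistinguishable". Identical or near-identical
target/control categories (membership Jaccard > 0.95) are rejected
rather than silently producing an ill-conditioned fit.

## Cross-trait conditioning

`b_xy` is the median over instruments (genome-wide-significant SNPs of
the conditioning trait at p < 5×10⁻⁸, strongest SNP per LD block) of the
ratio of standardized effects `b = z/√N`, with a delete-one-instrument
jackknife SE. Adjusted statistics are `b₁ − b_xy·b₂` with SEs inflated
by `√(1+b_xy²)` (non-overlapping samples assumed). This is a
deliberately lean estimator preserving the inferential contract — remove
the conditioning trait's mediated signal — without LD-aware joint SNP
modelling or genetic-correlation machinery. Two properties matter in
practice and are reflected in the validation design: (i) the ratio
estimator carries winner's-curse attenuation when instruments sit near
the significance threshold, so conditioning scenarios plant strong loci
(per-SNP variance 1.25×10⁻⁴, expected causal χ² ≈ 31); (ii) with a
contaminated instrument set (instruments from trait-specific loci where
the ratio ≈ 0), the median stays anchored on the shared loci only while
those dominate, so the shared set in the scenarios is about twice the
size of the specific sets. The conditional scenarios judge "retained" by
raw p < 0.05 and "lost" by non-significance after correcting for the
scenario's evaluated entries — the corrected-significance convention the
scans report throughout; the cross-disorder matrix itself reports BH-FDR
q over evaluated entries, with eligibility requiring both disorders at
least suggestive (p < 0.05) on the cell type in the marginal scan.

## PPI modules and GO

Cell-type networks are node-induced subgraphs of the global PPI graph on
the type's specificity set; isolated nodes are kept in the node list but
excluded from community detection. Modules come from unweighted
multi-level modularity optimization with seeded node-order shuffling
(the greedy sweep is order-dependent); modules with more than 30 genes
are retained and labelled `<type>_M1, M2, ...` by decreasing size. An
edge-weight column, if present, is parsed and ignored (logged). On all
≤ 8-node graphs in the test suite the optimizer attains the exhaustive
maximum modularity; on planted partitions (4 × 50 nodes, edge
probabilities 0.3 within / 0.01 between) it recovers the communities at
ARI ≥ 0.9 across seeds. GO over-representation is the one-sided
hypergeometric tail ("classic" Fisher; no term decorrelation), with the
induced network's genes as the universe.

## Synthetic GWAS model

Per LD block with exchangeable correlation `R` (r = 0.5 by default), the
z-vector is `R·(√N·β) + L·ε` with `L` the Cholesky factor — the standard
linear-model approximation for summary statistics. β is nonzero only at
SNPs of causal-set genes, drawn N(0, effect-variance); trait pairs share
identical β at a `shared_fraction` of shared-set genes. The default
genome is one chromosome of 200 independent blocks × 100 SNPs (10 kb
spacing, 500 kb inter-block gaps, 6 genes per block with variable
extents of ≥ 2 SNPs so gene length and SNP count vary as covariates
must). The genome layout depends only on `genome_seed`, so several
traits can be simulated on one genome with different noise seeds. Three
effect-variance scales are preset: weak (causal χ² ≈ 1.6, diffuse
polygenic enrichment), mid (≈ 11, top loci genome-wide significant) and
strong (≈ 31, instrument-grade loci).

## What the validation does and does not show

The generators match the analysis models by construction: NB counts for
the NB marker test, the MVN summary model for both association engines.
Passing therefore demonstrates correctness of the implementations,
calibration under the stated nulls, and power at the planted effect
sizes — not robustness to real-data pathologies the simulation omits:
ambient RNA and doublets, batch structure between samples, realistic
human LD (block sizes, allele-frequency-dependent architecture),
overlapping GWAS samples, annotation errors, or confounded functional
categories (the single-category LDSC baseline would be inadequate for
real heritability partitioning). Problem sizes (≈ 4,000-cell atlases,
20,000-SNP genomes, 10–50 replicate simulations per study) were chosen
as the smallest at which the planted effects are comfortably
identifiable, so every study runs on a laptop-class single core.

## Numerical and degenerate-input conventions

Coordinates are 0-based half-open internally (1-based inclusive accepted
behind a dialect flag); chromosome names are normalized (`chr1` → `1`);
strand is parsed but ignored by symmetric SNP windows. Gene p-values are
clipped to [1e-300, 1−1e-16] before the probit. Zero-variance genes
scale to zeros; zero-depth cells are a hard error (QC should have
removed them). Duplicate SNP ids keep the first occurrence (logged);
allele mismatches in trait pairs are resolved by swap or dropped.
Result files are written with fixed float precision and stable column
order, so identical configurations reproduce identical bytes, which the
run manifest records as SHA-256 hashes.
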