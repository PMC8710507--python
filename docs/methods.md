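# Methods

## Overview

`glutme` quantifies the immunometabolic split of glucose transport in the
tumor microenvironment: GLUT1 (*SLC2A1*) rides the cancer compartment,
GLUT3 (*SLC2A3*) the immune compartment, and the GLUT3-to-GLUT1 transcript
ratio (GLUTratio) summarizes the balance per sample or spot. Because no
public accession is bundled, every stage is validated on synthetic data in
which the quantity each stage should recover was planted explicitly.

## Generative models (synthetic data)

All three generators share one gene roster so bulk, single-cell and spatial
results are comparable: 13 reserved marker/effector genes (SLC2A1, SLC2A3,
EPCAM, GZMB, PRF1, GZMA, CD3D, CD8A, CD4, CD79A, IGHM, CD68, LYZ), 13
five-gene signature sets (the ten immune cell types of the ImmuneScore plus
hypoxia, glycolysis, OXPHOS), and i.i.d. background genes whose baseline
means are lognormal(2, 1); reserved genes sit at a baseline mean of 20.
Fifty background genes are annotated to chromosome "7", all others to "1".
Counts are gamma-Poisson (negative binomial) with variance mu + alpha*mu^2
and a single dispersion alpha = 0.3 — ordinary bulk/UMI over-dispersion.
Each generator is a pure function of its arguments including the seed.

**Bulk** (`generate_bulk_cohort`, default 200 samples x 500 genes, mean
library 50,000): sample s draws an immune fraction f_s ~ Uniform(0,1) and
gene means are the mixture (1-f_s)*mu_cancer + f_s*mu_immune. The immune
profile carries the full fold change (default 8) on SLC2A3, the granzyme/
perforin effectors and all ten immune signature sets; the cancer profile
carries it on SLC2A1, EPCAM and the hypoxia set. Tying hypoxia to the
cancer profile makes the expected dissociation recoverable: hypoxia
enrichment correlates positively with GLUT1 expression but not with
GLUTratio. Profiles are scaled by one common factor (not per-profile
normalized) so the stated mean ratios hold exactly; library size then
varies mildly with f, which CPM normalization removes downstream.

**Single cell** (`generate_sc_counts`, default 800 genes, mean library
5,000): four discrete types (cancer, T, B, myeloid). Cancer cells
over-express SLC2A1 (glut_effect) and EPCAM (marker_effect); immune types
over-express SLC2A3 (glut_effect) and their canonical markers
(marker_effect). Each immune signature set is attached to one compartment
(B cells -> B; CD4/CD8 T and NK -> T; the six myeloid-lineage sets ->
myeloid) and elevated at sqrt(marker_effect), as are the cytolytic
effectors in T cells: accompanying program genes separate the clusters
while the canonical markers keep the top of the fold-change ranking, and
the square root degenerates to 1 under the effect-null so null calibration
is preserved. With `chr7_gain`, all chromosome-7 genes are multiplied by
the gain in cancer cells only — a dosage CNA in the style of chromosome-7
gains in glioblastoma.

The default of 800 genes is a fidelity requirement, not a tuning knob: with
only ~300 genes the planted signature genes are ~20% of the transcriptome,
so the expression bins from which module-score control genes are drawn are
contaminated by effect-carrying genes, biasing the no-gain CNA null and
attenuating spatial module scores — an artifact real transcriptomes (where
signatures are a tiny fraction of genes) do not show.

**Spatial** (`generate_spatial_grid`, default 20x20 spots, 800 genes, mean
library 8,000): a tumor rectangle (immune fraction ~0.1 +- 0.05 jitter)
inside an immune-rich field (~0.7), with the bulk mixture model per spot
and integer row/column coordinates. Scores are coordinate-free; the
coordinates exist only so region-based checks can consult the truth.

## Scoring definitions

* **CPM**: column rescaled to 1e6. **Lognorm**: ln(1 + 1e4 * count/total)
  per cell.
* **ssGSEA** (per observation): genes ranked by decreasing expression (ties
  broken by gene id so the score is independent of gene order); the score
  is the sum over the ranked list of the difference between the in-set CDF
  weighted by rank^alpha (alpha = 0.25; average ranks under ties) and the
  uniform out-of-set CDF. No cross-sample rescaling — the score is strictly
  single-sample. A set that misses the universe or covers it entirely is
  rejected.
* **ImmuneScore**: the sum of the ssGSEA scores of exactly the ten named
  immune cell types.
* **Module score**: genes are cut into 24 equal-frequency bins by mean
  expression (falling back to max(2, n_genes/3) bins on small universes);
  each set gene draws 100 control genes from its bin (with replacement when
  the bin is smaller), and the score is mean(set) - mean(controls) per
  observation, with a seeded sampler.
* **GLUTratio**: (CPM_SLC2A3 + 1)/(CPM_SLC2A1 + 1); correlations are taken
  on log2 of the ratio, which symmetrizes reciprocal effects. The scale
  (CPM) and pseudocount (1) are package conventions.
* **Cytolytic score**: geometric mean of granzyme and perforin CPM (+1).
  Default pair (GZMB, PRF1); the classical construct's GZMA is available by
  argument since the field's nomenclature is not consistent.
* **CNA score**: the module score of all genes annotated to one chromosome
  (>= 5 required); a dosage gain raises it in the amplified cells.

## Single-cell chain

Lognorm -> 2000 HVGs by the variance-stabilizing criterion (lowess trend of
log10 variance on log10 mean, frac = 0.3; per-gene standardization by the
predicted sd, clipped at sqrt(n_cells); rank by variance of the clipped
values) -> per-gene z-scores clipped at +-10 -> PCA (10 components,
deterministic signs: each component's largest-magnitude loading is made
positive) -> kNN graph (k = 20, Euclidean in PC space, self included) with
Jaccard shared-neighbour edge weights pruned below 1/15 -> Louvain
modularity at a dataset-dependent resolution (0.2-1.0 in practice; 0.5 for
the synthetic four-type data), labels relabelled by decreasing cluster
size. Louvain draws from the stdlib RNG, which is re-seeded immediately
before the call, so identical inputs and seed give identical labels.

Markers: one-vs-rest Mann-Whitney per gene, log fold change defined as
ln((mean expm1 + 1) ratio), BH adjustment within each cluster's gene
family, rows ranked by fold change (top 5 reported per cluster). Pairwise
differential expression applies both gates: |logFC| > 0.25 and BH-FDR
< 0.05. Clusters of fewer than 3 cells are skipped with a logged warning.

Annotation: a cluster gets the cell type whose marker-set mean (lognorm) is
highest in the cluster **and** exceeds that set's all-cell mean; otherwise
`unknown`. Ties break by the fixed order cancer, Tcell, Bcell, myeloid.
Coarse classes: cancer = cancer-annotated clusters (marker mode) or the
high group of a 1-D two-means split of cluster-median CNA scores (CNA
mode, for EPCAM-negative tumors); immune = T/B/myeloid clusters; the rest
`other`, excluded from cancer-vs-immune contrasts.

## Spatial chain

For each anchor (SLC2A1, SLC2A3): Pearson correlation of every other gene
with the anchor across spots on the lognorm layer; the top 50 positively
correlated genes (anchor excluded — the module must not restate its
anchor; fewer with a logged warning if fewer are positive) define the
anchor's module, scored per spot with the binned-control module score.
ImmuneScore per spot comes from the same ssGSEA machinery on CPM; raw
EPCAM lognorm expression is carried as a column. Log-normalization is the
preprocessing for this stage; no variance-stabilizing regression of the
Visium type is attempted, since all spatial validation is against planted
truth rather than any published section.

## Statistical kernel

* **Mann-Whitney U**: U from rank sums; exact p by full enumeration of all
  C(n+m, n) labelings when both groups have <= 8 observations (valid under
  ties; a perfectly tied comparison returns p = 1 under the two-sided
  2*min(tails) convention), tie-corrected normal approximation without
  continuity correction otherwise. Empirical type-I error at nominal 0.05
  is ~0.049 over 10,000 null simulations (n = 20 per group).
* **Kruskal-Wallis**: tie-corrected H with a chi-squared tail on g-1 df
  (scipy); an all-equal input returns H = 0, p = 1.
* **Pearson**: r with the two-sided t-transform p on n-2 df (scipy);
  constant vectors are rejected.
* **BH-FDR**: statsmodels step-up, original order restored.
* **ORA**: upper-tail hypergeometric P(X >= overlap) per set after
  intersecting with the caller-supplied universe (no tool-internal universe
  exists here by design), BH across tested sets, gates p < 0.05 and
  FDR < 0.2. Equivalent to one-sided Fisher on the 2x2 table.
* Significance stars follow the usual ladder (* 0.05, ** 0.01, *** 0.001,
  **** 0.0001) on uncorrected p-values.

## Validation problem sizes

The test-suite and acceptance-script runs use: bulk 200 samples (20 seeds
for the effect-null control), single cell 2,000 cells (1,500 for CNA
calling, 80 cells x 40 seeds for marker null calibration), spatial 20x20
spots (20 seeds for the regional null), 10,000 Mann-Whitney null
simulations, and 100-1,000 instances per oracle comparison — sizes at
which every planted effect is comfortably detectable on one CPU in a few
minutes.

## What the synthetic data does not emulate

Discrete cell types only (no continuous states or gradients), no doublets,
ambient RNA, batch effects or spatial bleed-over; a single dispersion for
all genes; two-level immune fractions in the spatial grid; five-gene toy
signatures rather than curated ones; and the ten-type ImmuneScore is a
signature-sum, not a spillover-compensated deconvolution — so passing
tests demonstrate correctness of the machinery and recoverability of
planted effects, not performance on any real cohort. t-SNE is exposed only
as an optional visual aid and is not validated, since embeddings are not
contractually testable.
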