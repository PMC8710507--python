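# glutme

Glucose-transporter profiling of the tumor microenvironment (TME) across
bulk, single-cell and spatial transcriptomics.

## The problem

Cancer cells and tumor-infiltrating immune cells compete for glucose, but
they import it through different transporters: GLUT1 (*SLC2A1*) dominates in
cancer cells, GLUT3 (*SLC2A3*) in immune cells. The ratio of the two
transcripts,

```
GLUTratio = (CPM_SLC2A3 + 1) / (CPM_SLC2A1 + 1)
```

is therefore a candidate surrogate of immune (versus cancer) glucose
metabolism in a tumor sample. `glutme` implements the full analysis chain
needed to evaluate that statistic and its cellular basis:

* **Bulk cohorts** — CPM normalization, single-sample gene-set enrichment
  (ssGSEA, the Barbie-style rank-weighted running sum), a composite
  **ImmuneScore** (sum of enrichment scores for B cells, CD4+/CD8+ T-cells,
  dendritic cells, eosinophils, macrophages, mast cells, monocytes,
  neutrophils and NK cells), hypoxia and cytolytic scores, and Pearson
  correlation of each with log2 GLUTratio.
* **Single-cell data** — lognorm → variance-stabilized HVG selection →
  z-scaling → PCA → shared-nearest-neighbour graph → Louvain clustering →
  Mann-Whitney marker detection → marker-based cell-type annotation, plus a
  chromosome-level copy-number module score (the GBM-style chr7 dosage
  proxy) for calling cancer cells in EPCAM-negative tumors.
* **Spatial sections** — per-spot module scores built from each anchor
  gene's top-50 positively correlated genes, correlated spot-wise with
  ImmuneScore and EPCAM expression.
* **Synthetic data with planted truth** — negative-binomial generators for
  all three modalities in which the immune fraction, cell-type labels,
  marker effects and chromosome-7 gain are known, so every stage can be
  validated by recovery of its planted signal.

The fit/transform-shaped stages are scikit-learn-style estimators
(`SingleCellPipeline`, `SpatialModuleMapper`, `SSGSEAScorer`,
`ModuleScorer`) with plain functions as thin wrappers, so they compose with
sklearn tooling.

## Worked example

```python
import glutme as g

# a 200-sample bulk cohort whose immune fraction drives GLUT3 and the
# immune signatures, while GLUT1 tracks the cancer compartment
matrix, truth, _ = g.generate_bulk_cohort(n_samples=200, immune_effect=8, seed=1)
table = g.profile_bulk(matrix, g.builtin_signature_collection())
res = g.pearson_corr_test(table["log2_GLUTratio"], table["ImmuneScore"])
print(f"GLUTratio vs ImmuneScore: r = {res.statistic:.3f}, p = {res.p_value:.2e}")
```

prints

```
GLUTratio vs ImmuneScore: r = 0.682, p = 1.13e-28
```

i.e. samples with a larger planted immune fraction have both a higher
GLUT3/GLUT1 ratio and a higher composite immune enrichment — the
association the statistic is designed to capture. The single-cell chain
recovers the cellular basis of the same signal:

```python
m, truth, anno = g.generate_sc_counts(n_cells=2000, glut_effect=6,
                                      marker_effect=6, seed=1)
pipe = g.SingleCellPipeline(resolution=0.5, seed=1).fit(m)
print({c: pipe.assignment_.cell_type[c] for c in pipe.assignment_.clusters()})
# {0: 'cancer', 1: 'Tcell', 2: 'myeloid', 3: 'Bcell'}
```

with GLUT1 significantly higher in cancer cells (one-sided Mann-Whitney
p = 5.6e-284) and GLUT3 higher in immune cells.

The same pipeline is scriptable from the shell:

```sh
glutme --seed 1 --out-dir data simulate bulk
glutme --seed 1 --out-dir out score --matrix data/bulk.mtx \
    --genes data/bulk.genes.txt --obs data/bulk.obs.txt
```

All formats are plain text: MatrixMarket MTX with one-id-per-line sidecars,
GMT gene sets, TSV tables.

## Documentation

`docs/methods.md` describes the generative models, the scoring definitions,
the numerical conventions and the known limitations.
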