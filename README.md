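# scintbench

Benchmarking toolkit for single-cell data integration.

Combining scRNA-seq samples from different experiments, reagent batches
or technologies introduces batch effects that confound downstream
analysis. Many correction methods exist, their relative performance is
dataset-dependent, and they return different kinds of output — a
corrected expression matrix, a low-dimensional embedding, or a kNN
graph. `scintbench` is for analysts who need to pick among them: it
scores any of those output kinds with a two-category metric suite,
aggregates the scores into a ranking, ships three classical baseline
integrations (ComBat, MNN, BBKNN), and includes a ground-truth synthetic
generator so the whole loop runs with no external data.

## Metrics

Batch correction (mixing):

- **iLISI** — inverse Simpson's index of batch labels in
  perplexity-weighted neighborhoods, rescaled by (mean − 1)/(B − 1)
- **kBET** — per-cell χ² test of local vs global batch composition,
  reported as acceptance rate
- **Regression-PCA** — variance-weighted R² of principal components on
  batch, reported as the before/after comparison
  (PCR_before − PCR_after)/PCR_before
- **DPCA** — variance-weighted overlap ∫min(f_a, f_b) of per-batch
  kernel densities on PC scores
- **batch ASW** — mean of 1 − |s(i)| with batch as silhouette cluster,
  within cell-type groups

Bio-conservation:

- **cLISI** — neighborhood cell-type purity, (C − mean)/(C − 1)
- **NMI / ARI** — agreement of a Leiden clustering with the annotation
- **cell-type ASW** — (mean silhouette + 1)/2 over cell types
- **graph connectivity** — mean largest-component fraction of each
  type-induced subgraph
- **scGraph** — per-batch Spearman correlation of between-type centroid
  distances, reference vs integrated
- **cell-cycle conservation** — retention of S/G2M-score variance per
  batch, before vs after

Scores are oriented higher-is-better, min-max rescaled (on scores or on
ranks; ranks by default — stabler when methods come and go), averaged
per category, and combined as `overall = w_batch·batch + w_bio·bio`.
Metrics that need numerical components are not computed for
graph-returning methods; those cells are missing, not zero.

## Worked example

```python
import scintbench as sb

truth = sb.preset("shifted", seed=7)      # 4 batches x 250 cells, 6 types
ds = sb.simulate_counts(truth)            # NB counts + true latent embedding

outputs = [
    sb.run_method("combat", ds),                                      # matrix
    sb.run_method("mnn", ds, embedding_or_layer="latent_true",
                  k=20, sigma=3.0),                                   # embedding
    sb.run_method("bbknn", ds, k_per_batch=5),                        # graph
]
params = sb.ScoringParams(k=15, perplexity=20.0, n_pcs=10, seed=0)
table = sb.score_methods(ds, outputs, params=params)
print(table.to_frame().round(2))
cs = sb.composite(table, 0.5, 0.5, "minmax_ranks")
print(sb.overall_and_rank(cs).round(3))
```

Output:

```
              ilisi  kbet   pcr  dpca  asw_batch  clisi   nmi   ari  asw_celltype  graph_connectivity  scgraph
unintegrated   0.01  0.00  0.00  0.48       0.56   0.95  0.63  0.30          0.55                0.67     1.00
combat         0.55  0.65  1.00  0.90       0.91   0.96  0.90  0.92          0.62                1.00     0.94
mnn            0.34  0.21  0.71  0.77       0.87   0.94  0.74  0.68          0.60                1.00     0.97
bbknn          0.56  0.73   NaN   NaN        NaN   0.89  0.70  0.55           NaN                1.00      NaN

              batch_correction  bio_conservation  overall  rank
combat                   0.867             0.722    0.794     1
bbknn                    1.000             0.417    0.708     2
mnn                      0.433             0.556    0.494     3
unintegrated             0.000             0.278    0.139     4
```

Reading it: the unintegrated data mixes batches not at all (iLISI 0.01,
kBET acceptance 0) while keeping cell types trivially intact; ComBat
removes nearly all batch-explained PC variance (pcr 1.00) and improves
clustering agreement (ARI 0.30 → 0.92); BBKNN returns a graph, so the
PCA- and silhouette-based columns are missing by design and its
composites average over the remaining metrics. With equal weights ComBat
ranks first here.

The same loop is available from the shell:

```sh
scintbench simulate  --preset shifted --seed 7 --out bundle/
scintbench integrate --bundle bundle/ --method combat --method bbknn --out runs/
scintbench score     --bundle bundle/ --runs runs/ --out scores.csv
scintbench aggregate --scores scores.csv --rescale ranks
scintbench report    --scores scores.csv --kind dotplot --out scores.svg
```

Bundles are plain-text directories (MatrixMarket + TSV/CSV); score
tables round-trip through CSV or JSON with missing cells preserved.

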