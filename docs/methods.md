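# Methods

`scintbench` evaluates single-cell data-integration outputs. An
integration method consumes a multi-batch expression dataset and returns
one of three things: a corrected expression **matrix**, a low-dimensional
**embedding**, or a k-nearest-neighbor **graph**. The toolkit scores any
of these with two families of metrics — how well batches are mixed
(batch correction) and how well biological structure is preserved
(bio-conservation) — and aggregates the scores into composite and
overall values that rank methods.

## Metric definitions and numerical choices

All stored metric values are oriented higher-is-better and lie in
[0, 1]; each metric also keeps its native raw value.

**iLISI / cLISI.** For each cell, neighbor weights come from a Gaussian
kernel on squared distances, calibrated by binary search so the Shannon
entropy of the weights equals log2(perplexity) (tolerance 1e-5, at most
64 iterations; all-equal distances fall back to uniform weights). Label
probabilities are weight sums per label and the local diversity is the
inverse Simpson index 1/Σ p_b². iLISI (batch labels) is rescaled as
(mean − 1)/(B − 1); cLISI (cell-type labels) as (C − mean)/(C − 1).
Defaults: perplexity 30 over a 90-neighbor set, the original LISI
convention. Note a ceiling inherent to the statistic: even i.i.d. mixing
of B = 4 batches at perplexity 30 yields scaled iLISI ≈ 0.8, because
finite neighborhoods fluctuate around the global batch frequencies and
keep Σ p_b² above 1/B. Perfect scores are asymptotic, not attainable.

**kBET.** Per cell, a Pearson χ² test of the k-neighborhood batch
counts against expected counts k·f_b from the global batch frequencies,
df = B − 1; the raw metric is the rejection fraction at level α
(default 0.05) and the stored value is the acceptance rate. All cells
are tested (no subsampling) at the problem sizes this package targets.
Batches with zero global frequency are dropped; k·f_b < 1 triggers an
under-power warning.

**Regression-PCA.** PCA of the input (full SVD, deterministic sign
convention), then per-PC least-squares R² on the batch indicator,
averaged with PC variances as weights. The raw value is the fraction of
embedding variance explained by batch (lower-better); the score table
stores the before/after comparison clamp((raw_before − raw_after)/
raw_before, 0, 1) against the unintegrated reference, which is 0 when
nothing changed and 1 for complete batch-variance removal.

**DPCA.** Per PC and batch pair, two 1-D kernel density estimates
(Gaussian kernel, classical Silverman bandwidth 0.9·min(sd, IQR/1.34)·
n^(−1/5)) on a common 512-point grid spanning the pooled range ±3
bandwidths; the overlap integral ∫min(f_a, f_b) is averaged over pairs
and then over PCs with variance weights. This concrete construction is
one reasonable reading of "density overlap on principal components";
alternatives (shared grid across all batches, equal PC weights) would
shift values slightly but not orderings.

**Silhouette scores.** Cell-type ASW is the mean silhouette width with
cell types as clusters, rescaled (s + 1)/2. Batch ASW is computed within
each cell-type group containing at least two batches, as the mean of
1 − |s(i)| with batch as the cluster label (perfectly interleaved
batches give s ≈ 0, hence a score near 1), averaged over eligible
groups; with no eligible group the metric is missing. Silhouette widths
come from scikit-learn and are oracle-tested against the O(n²)
definition.

**Graph connectivity.** For each cell type, the fraction of its cells
in the largest connected component of the type-induced subgraph
(undirected view); the metric is the mean over types and equals 1 iff
every type is internally connected. Singleton types count as connected.

**scGraph.** Per batch with ≥ 3 cell types, type centroids are computed
in the unintegrated reference and in the integrated space; the Spearman
correlation between the two pairwise centroid-distance vectors measures
preservation of between-type geometry. Raw = mean correlation over
eligible batches, scaled (ρ + 1)/2. Invariant to rotation, translation
and uniform scaling of either space.

**Cell-cycle conservation.** S and G2M module scores are computed once
from expression (mean of the set minus mean of expression-matched
control genes drawn from 25 bins, 50 controls per gene, seeded). Per
batch, the variance the two scores explain in the before- and
after-integration spaces is measured with the same variance-weighted
PC-regression construction; the per-batch score is
1 − |V_after − V_before|/V_before clamped to [0, 1], averaged over
batches (V_before = 0 batches are skipped with a warning). Canonical
human S/G2M marker symbols are bundled as a convenience default; pass
organism-appropriate sets for real data.

**NMI / ARI.** Computed against a Leiden clustering of the
connectivity graph (RBConfiguration modularity, seeded, resolutions
{0.25, 0.5, 1, 2} by default, keeping the partition with the best NMI
against the annotation). NMI uses arithmetic-mean normalization; ARI's
raw value is signed and the stored value clamps chance-or-worse to 0.

## Graphs and connectivities

kNN graphs are exact (full pairwise search) up to 4096 cells with ties
broken toward the lower cell index, and tree-based above that (ties at
the k-boundary have probability zero for continuous embeddings). Two
distance→connectivity kernels are provided, both interpretations since
no canonical definition exists: `gaussian_adaptive`
(w_ij = exp(−d²/σ_i²), σ_i the ⌈k/2⌉-th neighbor distance, symmetrized
by maximum) and `umap_fuzzy_union` (local scaling to a fixed smoothed
degree, fuzzy union a + b − ab). The gaussian kernel is the default.

## Baseline integrations

**ComBat** (matrix output): genes are standardized against the
batch-design least-squares fit, per-batch location/scale effects are
estimated and shrunk by parametric empirical Bayes (normal prior on
location, inverse-gamma on scale, hyperparameters by method of moments,
fixed-point iteration to 1e-4 relative tolerance, ≤ 100 iterations),
removed, and the scale restored. Two deliberate choices: per-gene grand
means are restored exactly after adjustment (raw EB output drifts by
~1e-5 through shrinkage residuals), and a single-batch input is returned
unchanged rather than rejected. Constant genes pass through untouched.
ComBat is *not* strictly idempotent: a second application re-shrinks the
sampling noise of batch means and moves values by a small amount
(~1% of the original correction at 500 cells/batch) — a property of the
EB estimator itself, shared by other implementations.

**MNN** (matrix or embedding output): batches merge sequentially in
input order; mutual nearest pairs between the growing reference and the
incoming batch define difference vectors, and each incoming cell moves
by a Gaussian-kernel-weighted average of those vectors (distances to the
pairs' incoming-batch members, bandwidth `sigma`, default 1.0 in input
units — scale it with your data). Cells far from every pair fall back to
the unweighted mean correction. The method's accuracy rests on its
published assumption that the batch vector is near-orthogonal to the
biological subspace: when the shift lies inside the span of biological
variation, nearest-neighbor matching absorbs much of it and the
estimated correction is biased low.

**BBKNN** (graph output): each cell receives its k_per_batch nearest
neighbors within every batch, which forces cross-batch edges regardless
of separation; connectivities are attached with the gaussian kernel.

All three are deterministic; no random state is consumed.

## Scoring, aggregation, applicability

A scoring run derives what each metric needs from the output kind:
matrices are reduced by PCA (default 20 PCs), embeddings are used
directly, graphs are used as-is; a kNN graph (default k = 15) is built
from numerical outputs for the graph-based metrics. Metrics that require
numerical components (Regression-PCA, DPCA, both silhouettes, scGraph,
cell-cycle conservation) are not computed for graph outputs — the cell
is missing, not zero. An "unintegrated" row is always scored.

Aggregation orients every column higher-is-better, then min-max rescales
either the scores or their average ranks (default: ranks, which is
invariant to any strictly monotone transform of a column and therefore
more stable when methods are added or removed; a test demonstrates this
by perturbing one method's raw scores). Constant columns map to 0.5.
Composites are category means over available entries; the overall score
is w_batch·batch + w_bio·bio with default weights 0.5/0.5 (no published
default exists; the weights express user priorities and are
configurable). Ranking is descending by overall, ties broken by
bio-conservation then method name.

## Synthetic data

The generator factorizes into latent and count layers so metric
correctness can be tested without a preprocessing pipeline. Cells are a
Gaussian mixture: type centroids drawn once and scaled so their RMS
pairwise distance equals s (default 6), isotropic within-type noise
σ = 1, batch effects as latent shift vectors of norm m plus per-gene
additive (log-scale, sd 0.3) and multiplicative (sd 0.15) effects on the
count means. Counts are negative binomial (dispersion 2) with log-normal
library sizes (~10⁴); an optional cell-cycle program adds rectified
sin/cos phase signal to designated S/G2M gene sets. The exact shift
vectors are retained, so a perfect "oracle" integration (subtract the
true shifts) is available as an upper-bound reference.

Presets: `well_mixed` (4 × 250 cells, 6 types, m = 0), `shifted`
(same with m = 6), and `nested_atlas` (4 studies × 2 samples × 1250
cells = 10 000 cells, 17 types, study-level shifts of norm 6 with
within-study sample shifts of norm 2, cell-cycle program on) matching
the atlas-style design the toolkit is aimed at. Gene counts (400/800)
are realistic highly-variable-gene set sizes.

What the generator does **not** emulate: dropout/ambient RNA, doublets,
non-linear batch distortions, unbalanced type composition across
batches. Passing tests show the metrics and pipeline behave correctly
under the generative model's assumptions; they do not certify
performance on real tissue atlases.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale: toys of 4–60 cells
for analytic and oracle checks; 600–1000 cells for null calibrations;
500 cells/batch for ComBat recovery, 300/batch for MNN, 5000/batch for
the DPCA closed-form comparison; the end-to-end ordering uses the
shifted preset at 4 × 204 cells over 5 seeds. Every stochastic step
takes an explicit seed; the three baseline integrations are fully
deterministic.
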