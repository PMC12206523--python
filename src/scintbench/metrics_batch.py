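"""Batch-correction (mixing) metrics.

All metrics report a :class:`~scintbench.datamodel.MetricResult` whose
``value`` is oriented higher-is-better in [0, 1]:

* iLISI — perplexity-calibrated inverse Simpson's index of batch labels
  in each cell's neighborhood, rescaled by the batch count.
* kBET — per-cell Pearson chi-squared test of local vs global batch
  composition; stored value is the acceptance rate (1 - rejection rate).
* Regression-PCA — variance-weighted R^2 of principal components on the
  batch indicator (raw, lower-better) and its before/after comparison
  (oriented).
* DPCA — variance-weighted overlap of per-batch kernel density estimates
  on principal-component scores.
* batch-ASW — silhouette of batch labels within cell-type groups,
  converted so perfect mixing scores 1.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import chi2

from ._pcr import pc_scores, variance_weighted_r2
from .datamodel import MetricResult
from .neighbors import NeighborGraph, knn_graph

__all__ = [
    "lisi",
    "kbet",
    "kbet_cell_statistic",
    "pcr_batch",
    "pcr_comparison",
    "dpca",
    "density_overlap_1d",
    "batch_asw",
]


# ----------------------------------------------------------------------
# LISI core (shared with cLISI in metrics_bio)
# ----------------------------------------------------------------------

def _perplexity_weights(d: np.ndarray, perplexity: float,
                        tol: float = 1e-5, max_iter: int = 64) -> np.ndarray:
    """Gaussian kernel weights over one cell's neighbor distances,
    calibrated by binary search so the Shannon entropy (bits) of the
    weight distribution equals log2(perplexity)."""
    d2 = d.astype(np.float64) ** 2
    d2 = d2 - d2.min()
    if np.all(d2 == d2[0]):  # degenerate: all-equal distances
        return np.full(len(d), 1.0 / len(d))
    target = np.log2(perplexity)
    beta, beta_lo, beta_hi = 1.0, 0.0, np.inf

    def entropy_bits(beta: float) -> tuple[float, np.ndarray]:
        w = np.exp(-beta * d2)
        s = w.sum()
        p = w / s
        nz = p > 0
        return float(-(p[nz] * np.log2(p[nz])).sum()), p

    for _ in range(max_iter):
        h, p = entropy_bits(beta)
        if abs(h - target) < tol:
            break
        if h > target:  # too flat -> sharpen
            beta_lo = beta
            beta = beta * 2 if np.isinf(beta_hi) else (beta + beta_hi) / 2
        else:
            beta_hi = beta
            beta = beta / 2 if beta_lo == 0 else (beta + beta_lo) / 2
    return p


def _neighborhoods(g_or_embedding, k: int):
    """(indices, distances) rows for each cell, from a graph or embedding."""
    if isinstance(g_or_embedding, NeighborGraph):
        g = g_or_embedding
        order = np.lexsort((g.dst, g.dist, g.src))
        src_s, dst_s, dist_s = g.src[order], g.dst[order], g.dist[order]
        starts = np.searchsorted(src_s, np.arange(g.n_cells))
        ends = np.searchsorted(src_s, np.arange(g.n_cells) + 1)
        idx_l = [dst_s[a:b] for a, b in zip(starts, ends)]
        d_l = [dist_s[a:b] for a, b in zip(starts, ends)]
        return idx_l, d_l
    g = knn_graph(np.asarray(g_or_embedding, dtype=np.float64), k)
    idx, dd = g.neighbor_matrix()
    return list(idx), list(dd)


def lisi_per_cell(g_or_embedding, labels: np.ndarray, perplexity: float = 30.0
                  ) -> np.ndarray:
    """Per-cell inverse Simpson's index of ``labels`` under
    perplexity-calibrated neighbor weights. Values lie in [1, B]."""
    codes = np.unique(labels, return_inverse=True)[1]
    n = len(codes)
    k = min(int(np.ceil(3 * perplexity)), n - 1)
    idx_l, d_l = _neighborhoods(g_or_embedding, k)
    out = np.empty(n)
    for i in range(n):
        p = _perplexity_weights(d_l[i], perplexity)
        pb = np.bincount(codes[idx_l[i]], weights=p)
        out[i] = 1.0 / (pb**2).sum()
    return out


def lisi(g_or_embedding, labels, perplexity: float = 30.0) -> MetricResult:
    """Mean iLISI over cells with min-max rescaling by the label count.

    Raw value in [1, B]; scaled value (mean - 1) / (B - 1) is 1 for
    perfect mixing of B equally likely batches, 0 for none.
    """
    labels = np.asarray(labels)
    B = len(np.unique(labels))
    if B < 2:
        warnings.warn("LISI with a single label level is trivially 1")
        return MetricResult("ilisi", 1.0, 0.0, params={"perplexity": perplexity})
    per_cell = lisi_per_cell(g_or_embedding, labels, perplexity)
    raw = float(per_cell.mean())
    scaled = float(np.clip((raw - 1.0) / (B - 1.0), 0.0, 1.0))
    return MetricResult("ilisi", raw, scaled, per_cell,
                        {"perplexity": perplexity, "n_labels": B})


# ----------------------------------------------------------------------
# kBET
# ----------------------------------------------------------------------

def kbet_cell_statistic(observed: np.ndarray, freqs: np.ndarray
                        ) -> tuple[float, float]:
    """Pearson chi-squared statistic and p-value for one neighborhood's
    batch counts against expected counts k*f_b, df = B - 1."""
    observed = np.asarray(observed, dtype=np.float64)
    freqs = np.asarray(freqs, dtype=np.float64)
    k = observed.sum()
    expected = k * freqs
    stat = float(((observed - expected) ** 2 / expected).sum())
    df = len(freqs) - 1
    return stat, float(chi2.sf(stat, df))


def kbet(g: NeighborGraph, batch_labels, alpha: float = 0.05) -> MetricResult:
    """k-nearest-neighbor batch-effect test.

    Each cell's k-neighborhood batch composition is tested against the
    global batch frequencies with a Pearson chi-squared test; the raw
    metric is the fraction of cells rejected at level ``alpha``, and the
    stored (oriented) value is the acceptance rate 1 - rejection.
    """
    codes = np.unique(np.asarray(batch_labels), return_inverse=True)[1]
    B = codes.max() + 1
    freqs = np.bincount(codes, minlength=B) / len(codes)
    keep = freqs > 0
    freqs = freqs[keep]
    deg = np.bincount(g.src, minlength=g.n_cells)
    k_typ = int(np.median(deg[deg > 0]))
    if np.any(k_typ * freqs < 1):
        warnings.warn("kBET under-powered: some expected count k*f_b < 1")
    counts = np.zeros((g.n_cells, B))
    np.add.at(counts, (g.src, codes[g.dst]), 1.0)
    counts = counts[:, keep]
    k_i = counts.sum(axis=1)
    tested = k_i > 0
    expected = k_i[tested, None] * freqs[None, :]
    stats = (((counts[tested] - expected) ** 2) / expected).sum(axis=1)
    pvals = chi2.sf(stats, len(freqs) - 1)
    rejected = pvals < alpha
    rate = float(rejected.mean())
    return MetricResult("kbet", rate, 1.0 - rate, rejected.astype(float),
                        {"alpha": alpha, "k": k_typ, "n_batches": int(keep.sum())})


# ----------------------------------------------------------------------
# Regression-PCA
# ----------------------------------------------------------------------

def _one_hot(labels) -> np.ndarray:
    codes = np.unique(np.asarray(labels), return_inverse=True)[1]
    B = codes.max() + 1
    oh = np.zeros((len(codes), B))
    oh[np.arange(len(codes)), codes] = 1.0
    return oh[:, :-1]  # drop one level; intercept added downstream


def pcr_batch(X: np.ndarray, batch_labels, n_pcs: int = 50) -> MetricResult:
    """Variance explained by batch via principal-component regression.

    Raw value = sum_j var_j * R^2_j / sum_j var_j over the first n_pcs
    PCs of X, regressing each PC's scores on the batch indicator. Raw is
    lower-better (0 = no batch signal); the stored value is 1 - raw.
    """
    scores, var = pc_scores(np.asarray(X, dtype=np.float64), n_pcs)
    raw = variance_weighted_r2(scores, var, _one_hot(batch_labels))
    return MetricResult("pcr_raw", raw, 1.0 - raw,
                        params={"n_pcs": scores.shape[1]})


def pcr_comparison(X_before, X_after, batch_labels, n_pcs: int = 50
                   ) -> MetricResult:
    """Fraction of batch-explained variance removed by integration:
    clamp((raw_before - raw_after) / raw_before, 0, 1)."""
    before = pcr_batch(X_before, batch_labels, n_pcs).raw
    after = pcr_batch(X_after, batch_labels, n_pcs).raw
    if before <= 0:
        warnings.warn("no batch variance before integration; PCR comparison = 0")
        score = 0.0
    else:
        score = float(np.clip((before - after) / before, 0.0, 1.0))
    return MetricResult("pcr", score, score,
                        params={"n_pcs": n_pcs, "raw_before": before,
                                "raw_after": after})


# ----------------------------------------------------------------------
# DPCA
# ----------------------------------------------------------------------

def _silverman_bw(x: np.ndarray) -> float:
    n = len(x)
    sd = x.std(ddof=1) if n > 1 else 0.0
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        spread = max(sd, 1e-12)
    return 0.9 * spread * n ** (-0.2)


def density_overlap_1d(a: np.ndarray, b: np.ndarray, grid_size: int = 512
                       ) -> float:
    """Overlap integral of two 1-D Silverman-bandwidth Gaussian KDEs on a
    common grid spanning the pooled range plus 3 bandwidths."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    bw_a, bw_b = _silverman_bw(a), _silverman_bw(b)
    pad = 3 * max(bw_a, bw_b, 1e-12)
    lo = min(a.min(), b.min()) - pad
    hi = max(a.max(), b.max()) + pad
    grid = np.linspace(lo, hi, grid_size)

    def kde(x: np.ndarray, bw: float) -> np.ndarray:
        bw = max(bw, 1e-12)
        z = (grid[:, None] - x[None, :]) / bw
        return np.exp(-0.5 * z**2).sum(axis=1) / (len(x) * bw * np.sqrt(2 * np.pi))

    return float(np.trapezoid(np.minimum(kde(a, bw_a), kde(b, bw_b)), grid))


def dpca(X_scores: np.ndarray, batch_labels, variances: np.ndarray | None = None
         ) -> MetricResult:
    """Density overlap of per-batch PC score distributions.

    For each PC and each batch pair, the overlap integral of the two 1-D
    KDEs; per-PC overlaps (mean over pairs) are averaged with PC
    variances as weights. 1 = identical distributions, 0 = disjoint.
    """
    X = np.asarray(X_scores, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    codes = np.unique(np.asarray(batch_labels), return_inverse=True)[1]
    sizes = np.bincount(codes)
    eligible = np.flatnonzero(sizes >= 2)
    if len(eligible) < 2:
        raise ValueError("DPCA needs at least two batches with >= 2 cells")
    if len(eligible) < len(sizes):
        warnings.warn("batches with < 2 cells excluded from DPCA pairs")
    var = (np.asarray(variances, dtype=np.float64)
           if variances is not None else X.var(axis=0, ddof=1))
    per_pc = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        overlaps = [
            density_overlap_1d(X[codes == a, j], X[codes == b, j])
            for ai, a in enumerate(eligible)
            for b in eligible[ai + 1:]
        ]
        per_pc[j] = np.mean(overlaps)
    raw = float(np.clip((var * per_pc).sum() / var.sum(), 0.0, 1.0))
    return MetricResult("dpca", raw, raw, per_pc,
                        {"n_pcs": X.shape[1], "n_batches": len(eligible)})


# ----------------------------------------------------------------------
# batch ASW
# ----------------------------------------------------------------------

def batch_asw(embedding: np.ndarray, batch_labels, celltype_labels
              ) -> MetricResult:
    """Batch silhouette within cell-type groups.

    For every cell-type group containing >= 2 batches, silhouette widths
    s(i) are computed with batch as the cluster label and converted to
    1 - |s(i)| so that perfectly interleaved batches score 1. The raw
    value is the mean over eligible groups; with no eligible group the
    metric is missing (NaN).
    """
    from sklearn.metrics import silhouette_samples

    X = np.asarray(embedding, dtype=np.float64)
    batch = np.asarray(batch_labels)
    ct = np.asarray(celltype_labels)
    group_scores = []
    for g in np.unique(ct):
        m = ct == g
        labs = batch[m]
        n_lab = len(np.unique(labs))
        if n_lab < 2 or m.sum() <= n_lab:
            continue
        s = silhouette_samples(X[m], labs)
        group_scores.append(float(np.mean(1.0 - np.abs(s))))
    if not group_scores:
        return MetricResult("asw_batch", np.nan, np.nan)
    raw = float(np.mean(group_scores))
    return MetricResult("asw_batch", raw, raw, np.asarray(group_scores),
                        {"n_groups": len(group_scores)})
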