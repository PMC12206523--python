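"""Baseline batch-integration methods implemented from scratch.

Three classical approaches, one per output kind:

* ComBat — empirical-Bayes location/scale adjustment of an expression
  matrix (parametric priors: normal on additive batch effects,
  inverse-gamma on multiplicative ones).
* MNN — mutual-nearest-neighbor correction of a matrix or embedding;
  batches are merged sequentially and each incoming cell receives a
  Gaussian-kernel-smoothed average of nearby pair correction vectors.
* BBKNN — batch-balanced kNN graph: every cell is connected to its
  nearest neighbors *within each batch*, forcing cross-batch edges.

All three are deterministic; no random state is consumed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .datamodel import CellDataset, IntegrationOutput
from .neighbors import NeighborGraph, connectivities_from_distances, knn_graph

__all__ = [
    "CombatModel",
    "MnnCorrection",
    "combat_fit_transform",
    "mnn_correct",
    "bbknn_edges",
    "bbknn_graph",
    "METHOD_REGISTRY",
    "run_method",
]

log = logging.getLogger(__name__)


# ======================================================================
# ComBat
# ======================================================================

@dataclass
class CombatModel:
    """Fitted ComBat parameters.

    alpha: per-gene grand mean; gamma_star/delta_star: EB-shrunk
    additive/multiplicative batch effects (batches x genes); pooled_var:
    per-gene pooled variance of the standardized model residuals.
    """

    alpha: np.ndarray
    gamma_star: np.ndarray
    delta_star: np.ndarray
    pooled_var: np.ndarray
    batch_levels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(self.delta_star <= 0):
            raise ValueError("multiplicative batch effects must be positive")


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var()
    return (2 * s2 + m**2) / s2 if s2 > 0 else np.inf


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var()
    return (m * s2 + m**3) / s2 if s2 > 0 else np.inf


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _it_sol(Z_b, g_hat, d_hat, g_bar, t2, a, b, rtol=1e-4, maxit=100):
    """Fixed-point EB solution for one batch (genes vectorized)."""
    n = Z_b.shape[0]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(maxit):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = ((Z_b - g_new[None, :]) ** 2).sum(axis=0)
        d_new = _postvar(sum2, n, a, b)
        change = max(
            np.abs(g_new - g_old).max() / max(np.abs(g_old).max(), 1e-12),
            np.abs(d_new - d_old).max() / np.abs(d_old).max(),
        )
        g_old, d_old = g_new, d_new
        if change < rtol:
            break
    return g_old, d_old


def combat_fit_transform(
    ds: CellDataset,
    layer: str = "data",
    batch_key: str | None = None,
    parametric: bool = True,
    covariates: np.ndarray | None = None,
) -> IntegrationOutput:
    """Remove additive and multiplicative per-gene batch effects.

    Genes are standardized (grand mean and optional covariate effects
    removed, divided by the pooled SD), per-batch location/scale effects
    are estimated and shrunk toward their across-gene prior by parametric
    empirical Bayes, then removed and the original scale restored.

    Single-batch input is returned unchanged (nothing to correct);
    constant genes are passed through untouched.
    """
    if not parametric:
        raise NotImplementedError("only the parametric EB variant is provided")
    if layer not in ds.layers:
        raise KeyError(f"layer {layer!r} not in dataset")
    X = ds.layer_dense(layer).astype(np.float64)
    batches = ds.batch_codes()
    levels = list(ds.batch.categories)
    n_batches = len(levels)
    n_cells, n_genes = X.shape

    if n_batches < 2:
        return IntegrationOutput("combat", "matrix", X.copy())

    counts = np.bincount(batches, minlength=n_batches)
    for b, c in enumerate(counts):
        if c < 2:
            raise ValueError(
                f"batch {levels[b]!r} has {c} cell(s); ComBat needs >= 2 per batch"
            )

    # design: batch one-hots (+ optional covariates)
    design = np.zeros((n_cells, n_batches))
    design[np.arange(n_cells), batches] = 1.0
    if covariates is not None:
        cov = np.asarray(covariates, dtype=np.float64)
        cov = cov - cov.mean(axis=0, keepdims=True)
        design = np.hstack([design, cov])

    B_hat, *_ = np.linalg.lstsq(design, X, rcond=None)
    grand_mean = (counts / n_cells) @ B_hat[:n_batches]
    fitted = design @ B_hat
    pooled_var = ((X - fitted) ** 2).mean(axis=0)

    const = pooled_var <= 1e-300
    if const.any():
        log.warning("%d constant gene(s) left unchanged by ComBat", int(const.sum()))
    sd = np.sqrt(np.where(const, 1.0, pooled_var))

    stand_mean = grand_mean[None, :]
    if covariates is not None:
        stand_mean = stand_mean + (design[:, n_batches:] @ B_hat[n_batches:])
    Z = (X - stand_mean) / sd[None, :]

    gamma_hat = np.stack([Z[batches == b].mean(axis=0) for b in range(n_batches)])
    delta_hat = np.stack(
        [Z[batches == b].var(axis=0, ddof=1) for b in range(n_batches)]
    )
    delta_hat = np.maximum(delta_hat, 1e-12)

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    for b in range(n_batches):
        g_bar, t2 = gamma_hat[b].mean(), gamma_hat[b].var()
        a, bb = _aprior(delta_hat[b]), _bprior(delta_hat[b])
        if t2 <= 0 or not np.isfinite(a):
            gamma_star[b], delta_star[b] = gamma_hat[b], delta_hat[b]
            continue
        gamma_star[b], delta_star[b] = _it_sol(
            Z[batches == b], gamma_hat[b], delta_hat[b], g_bar, t2, a, bb
        )
    delta_star = np.maximum(delta_star, 1e-12)

    Z_adj = (Z - gamma_star[batches]) / np.sqrt(delta_star[batches])
    out = Z_adj * sd[None, :] + stand_mean
    # EB shrinkage leaves a small residual in the overall location;
    # restore per-gene grand means exactly
    out += X.mean(axis=0) - out.mean(axis=0)
    out[:, const] = X[:, const]

    model = CombatModel(grand_mean, gamma_star, delta_star, pooled_var, levels)
    result = IntegrationOutput("combat", "matrix", out)
    result.model = model  # type: ignore[attr-defined]
    return result


# ======================================================================
# MNN
# ======================================================================

@dataclass
class MnnCorrection:
    """Mutual pairs and smoothed correction vectors for one merge step."""

    pairs: np.ndarray  # (n_pairs, 2): (index in reference, index in incoming)
    corrections: np.ndarray  # per incoming cell, in input space
    sigma: float


def _mutual_pairs(R: np.ndarray, T: np.ndarray, k: int) -> np.ndarray:
    """Cross-batch mutual nearest pairs between reference R and target T."""
    D = cdist(T, R)  # targets x refs
    k_r = min(k, R.shape[0])
    k_t = min(k, T.shape[0])
    cols_R = np.arange(R.shape[0])
    cols_T = np.arange(T.shape[0])
    nn_of_t = [set(np.lexsort((cols_R, D[t]))[:k_r]) for t in range(T.shape[0])]
    nn_of_r = [set(np.lexsort((cols_T, D[:, r]))[:k_t]) for r in range(R.shape[0])]
    pairs = [
        (r, t)
        for t in range(T.shape[0])
        for r in nn_of_t[t]
        if t in nn_of_r[r]
    ]
    return np.array(sorted(pairs), dtype=np.int64).reshape(-1, 2)


def mnn_correct(
    ds: CellDataset,
    embedding_or_layer: str = "data",
    batch_key: str | None = None,
    k: int = 20,
    sigma: float = 1.0,
    cosine_normalize: bool = False,
) -> IntegrationOutput:
    """Mutual-nearest-neighbor batch correction.

    Batches are merged in input order. At each merge, mutual nearest
    pairs between the growing (already corrected) reference and the
    incoming batch define per-pair difference vectors; every incoming
    cell is moved by a Gaussian-kernel weighted average of those vectors,
    with kernel distances measured from the incoming cell to each pair's
    incoming-batch member and bandwidth ``sigma``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if embedding_or_layer in ds.layers:
        X = ds.layer_dense(embedding_or_layer).astype(np.float64)
        kind = "matrix"
    elif embedding_or_layer in ds.embeddings:
        X = np.asarray(ds.embeddings[embedding_or_layer], dtype=np.float64)
        kind = "embedding"
    else:
        raise KeyError(f"{embedding_or_layer!r} is neither a layer nor an embedding")
    if cosine_normalize:
        norms = np.linalg.norm(X, axis=1, keepdims=True)
        X = X / np.where(norms == 0, 1.0, norms)

    batches = ds.batch_codes()
    levels = list(ds.batch.categories)
    if len(levels) < 2:
        raise ValueError("MNN needs at least two batches")

    out = X.copy()
    ref_mask = batches == 0
    corrections_log: list[MnnCorrection] = []
    for b in range(1, len(levels)):
        tgt_idx = np.flatnonzero(batches == b)
        R = out[ref_mask]
        T = out[tgt_idx]
        pairs = _mutual_pairs(R, T, k)
        if len(pairs) == 0:
            raise ValueError(
                f"no mutual nearest pairs between reference and batch "
                f"{levels[b]!r}; try a larger k"
            )
        vec = R[pairs[:, 0]] - T[pairs[:, 1]]  # correction direction
        anchors = T[pairs[:, 1]]
        d2 = cdist(T, anchors) ** 2
        w = np.exp(-d2 / (2.0 * sigma**2))
        wsum = w.sum(axis=1, keepdims=True)
        # a cell far from every anchor falls back to the unweighted mean
        far = wsum[:, 0] <= 1e-300
        w = np.where(far[:, None], 1.0, w)
        wsum = w.sum(axis=1, keepdims=True)
        corr = (w @ vec) / wsum
        out[tgt_idx] = T + corr
        corrections_log.append(MnnCorrection(pairs, corr, sigma))
        ref_mask = ref_mask | (batches == b)

    result = IntegrationOutput("mnn", kind, out)
    result.corrections = corrections_log  # type: ignore[attr-defined]
    return result


# ======================================================================
# BBKNN
# ======================================================================

def bbknn_edges(
    embedding: np.ndarray, batch_labels: np.ndarray, k_per_batch: int = 3
) -> NeighborGraph:
    """Raw directed batch-balanced edge set with distances.

    Every cell gets out-edges to its ``k_per_batch`` nearest cells within
    each batch (fewer when a batch is smaller), ties broken toward the
    lower cell index.
    """
    if k_per_batch < 1:
        raise ValueError("k_per_batch must be >= 1")
    X = np.asarray(embedding, dtype=np.float64)
    labels = np.asarray(batch_labels)
    levels, codes = np.unique(labels, return_inverse=True)
    n = X.shape[0]
    src_l: list[np.ndarray] = []
    dst_l: list[np.ndarray] = []
    dist_l: list[np.ndarray] = []
    for b in range(len(levels)):
        members = np.flatnonzero(codes == b)
        D = cdist(X, X[members])
        cols = np.arange(len(members))
        for i in range(n):
            d = D[i].copy()
            self_pos = np.flatnonzero(members == i)
            if len(self_pos):
                d[self_pos[0]] = np.inf
            avail = len(members) - (1 if len(self_pos) else 0)
            kk = min(k_per_batch, avail)
            if kk == 0:
                continue
            order = np.lexsort((cols, d))[:kk]
            src_l.append(np.full(kk, i, dtype=np.int64))
            dst_l.append(members[order])
            dist_l.append(d[order])
    return NeighborGraph(
        n_cells=n,
        k=k_per_batch * len(levels),
        src=np.concatenate(src_l),
        dst=np.concatenate(dst_l),
        dist=np.concatenate(dist_l),
    )


def bbknn_graph(
    embedding: np.ndarray,
    batch_labels: np.ndarray,
    k_per_batch: int = 3,
    connectivity_mode: str = "gaussian_adaptive",
) -> IntegrationOutput:
    """Batch-balanced kNN graph with connectivities.

    Builds the :func:`bbknn_edges` edge set — which guarantees
    cross-batch edges regardless of batch separation — then attaches
    connectivities via :func:`connectivities_from_distances`.
    """
    g = bbknn_edges(embedding, batch_labels, k_per_batch)
    g = connectivities_from_distances(g, mode=connectivity_mode)
    return IntegrationOutput("bbknn", "graph", g)


# ======================================================================
# registry
# ======================================================================

def _run_combat(ds: CellDataset, **kw) -> IntegrationOutput:
    layer = kw.pop("layer", "data" if "data" in ds.layers else next(iter(ds.layers)))
    return combat_fit_transform(ds, layer=layer, **kw)


def _run_mnn(ds: CellDataset, **kw) -> IntegrationOutput:
    src = kw.pop("embedding_or_layer", None)
    if src is None:
        src = next(iter(ds.embeddings), None) or next(iter(ds.layers))
    return mnn_correct(ds, embedding_or_layer=src, **kw)


def _run_bbknn(ds: CellDataset, **kw) -> IntegrationOutput:
    emb = kw.pop("embedding", None)
    if emb is None:
        name = next(iter(ds.embeddings), None)
        if name is None:
            raise ValueError("BBKNN needs an embedding")
        emb = ds.embeddings[name]
    return bbknn_graph(emb, np.asarray(ds.batch), **kw)


METHOD_REGISTRY = {
    "combat": _run_combat,
    "mnn": _run_mnn,
    "bbknn": _run_bbknn,
}


def run_method(name: str, ds: CellDataset, **kwargs) -> IntegrationOutput:
    """Dispatch an integration method by registry name."""
    if name not in METHOD_REGISTRY:
        raise KeyError(
            f"unknown method {name!r}; available: {sorted(METHOD_REGISTRY)}"
        )
    return METHOD_REGISTRY[name](ds, **kwargs)
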