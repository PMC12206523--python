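"""k-nearest-neighbor graphs and distance-to-connectivity kernels.

The NeighborGraph is the common currency of the graph-based metrics
(LISI, kBET, graph connectivity) and of graph-returning integration
methods such as batch-balanced kNN. Edges are kept as explicit arrays so
that zero-distance edges (duplicate cells) survive; sparse-matrix views
are built on demand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components as _cc

__all__ = [
    "NeighborGraph",
    "knn_graph",
    "connectivities_from_distances",
    "directed_kernel_weights",
    "connected_components",
]

# above this cell count the exact lexsort-based search would need an
# n x n distance matrix; fall back to sklearn's tree/brute search
_EXACT_KNN_MAX_N = 4096


@dataclass
class NeighborGraph:
    """Sparse directed or symmetrized kNN structure.

    Parameters
    ----------
    n_cells
        Number of cells (nodes).
    k
        Target out-degree used at construction time (cells may have a
        different degree, e.g. after symmetrization or batch-balanced
        construction).
    src, dst
        Edge endpoint indices, ``dst[e]`` is a neighbor of ``src[e]``.
    dist
        Per-edge distance, >= 0.
    conn
        Optional per-edge connectivity in (0, 1]; either present for all
        edges or absent.
    directed
        False once the edge set is symmetric (u->v implies v->u).
    """

    n_cells: int
    k: int
    src: np.ndarray
    dst: np.ndarray
    dist: np.ndarray
    conn: np.ndarray | None = None
    directed: bool = True

    def __post_init__(self) -> None:
        self.src = np.asarray(self.src, dtype=np.int64)
        self.dst = np.asarray(self.dst, dtype=np.int64)
        self.dist = np.asarray(self.dist, dtype=np.float64)
        if self.conn is not None:
            self.conn = np.asarray(self.conn, dtype=np.float64)
        if np.any(self.src == self.dst):
            raise ValueError("self-edges are not allowed in a NeighborGraph")
        if np.any(self.dist < 0):
            raise ValueError("edge distances must be non-negative")
        if self.conn is not None and len(self.conn) != len(self.src):
            raise ValueError("connectivities must cover every stored edge")

    @property
    def n_edges(self) -> int:
        return len(self.src)

    def neighbors_of(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """Out-neighbors of cell ``i`` and their distances, sorted by
        (distance, index)."""
        m = self.src == i
        d, j = self.dist[m], self.dst[m]
        order = np.lexsort((j, d))
        return j[order], d[order]

    def adjacency(self, weights: str = "binary") -> sp.csr_matrix:
        """CSR view of the edge set.

        weights: "binary" (1 per edge), "distance", or "connectivity".
        Zero distances are shifted by nothing — binary/connectivity views
        are safe for structure queries; the "distance" view may drop
        exact-zero entries and is only for weighted algorithms.
        """
        if weights == "binary":
            data = np.ones(self.n_edges)
        elif weights == "distance":
            data = self.dist
        elif weights == "connectivity":
            if self.conn is None:
                raise ValueError("graph has no connectivities")
            data = self.conn
        else:  # pragma: no cover
            raise ValueError(f"unknown weights kind {weights!r}")
        return sp.csr_matrix(
            (data, (self.src, self.dst)), shape=(self.n_cells, self.n_cells)
        )

    def neighbor_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """(indices, distances) arrays of shape (n_cells, deg) for graphs
        with uniform out-degree, rows sorted by (distance, index)."""
        counts = np.bincount(self.src, minlength=self.n_cells)
        deg = counts[0] if len(counts) else 0
        if not np.all(counts == deg):
            raise ValueError("graph does not have uniform out-degree")
        order = np.lexsort((self.dst, self.dist, self.src))
        idx = self.dst[order].reshape(self.n_cells, deg)
        dd = self.dist[order].reshape(self.n_cells, deg)
        return idx, dd


def _knn_exact(X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Brute-force kNN with deterministic (distance, index) tie-break."""
    from scipy.spatial.distance import cdist

    n = X.shape[0]
    D = cdist(X, X)
    np.fill_diagonal(D, np.inf)
    cols = np.arange(n)
    idx = np.empty((n, k), dtype=np.int64)
    dd = np.empty((n, k))
    for i in range(n):
        order = np.lexsort((cols, D[i]))[:k]
        idx[i] = order
        dd[i] = D[i, order]
    return idx, dd


def knn_graph(embedding: np.ndarray, k: int, metric: str = "euclidean") -> NeighborGraph:
    """Exact k-nearest-neighbor digraph of an embedding.

    Each cell gets out-edges to its ``k`` nearest other cells; ties at
    equal distance are broken toward the lower cell index.
    """
    X = np.asarray(embedding, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("embedding must be 2-D (cells x dims)")
    if metric != "euclidean":
        raise ValueError(f"unsupported metric {metric!r}")
    n = X.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    if k < 1:
        raise ValueError("k must be >= 1")
    if n <= _EXACT_KNN_MAX_N:
        idx, dd = _knn_exact(X, k)
    else:
        from sklearn.neighbors import NearestNeighbors

        nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
        dd, idx = nn.kneighbors(X)
        # drop self-column wherever it appears
        keep_idx = np.empty((n, k), dtype=np.int64)
        keep_dd = np.empty((n, k))
        for i in range(n):
            m = idx[i] != i
            keep_idx[i] = idx[i, m][:k]
            keep_dd[i] = dd[i, m][:k]
        idx, dd = keep_idx, keep_dd
    src = np.repeat(np.arange(n, dtype=np.int64), k)
    return NeighborGraph(n, k, src, idx.ravel(), dd.ravel())


def _symmetrize_max(
    n: int, src: np.ndarray, dst: np.ndarray, w: np.ndarray, dist: np.ndarray
) -> NeighborGraph:
    """Union of edge sets; weight and distance of a mutual edge = max /
    stored distance (distances agree for mutual metric edges)."""
    key = {}
    for s, d, ww, dd in zip(src, dst, w, dist):
        a, b = (int(s), int(d)) if s < d else (int(d), int(s))
        prev = key.get((a, b))
        if prev is None or ww > prev[0]:
            key[(a, b)] = (ww, dd)
    m = len(key)
    out_src = np.empty(2 * m, dtype=np.int64)
    out_dst = np.empty(2 * m, dtype=np.int64)
    out_w = np.empty(2 * m)
    out_d = np.empty(2 * m)
    for e, ((a, b), (ww, dd)) in enumerate(sorted(key.items())):
        out_src[2 * e], out_dst[2 * e] = a, b
        out_src[2 * e + 1], out_dst[2 * e + 1] = b, a
        out_w[2 * e] = out_w[2 * e + 1] = ww
        out_d[2 * e] = out_d[2 * e + 1] = dd
    return NeighborGraph(n, 0, out_src, out_dst, out_d, conn=out_w, directed=False)


def connectivities_from_distances(
    g: NeighborGraph, mode: str = "gaussian_adaptive"
) -> NeighborGraph:
    """Convert per-edge distances into connectivities in (0, 1].

    gaussian_adaptive
        ``w_ij = exp(-d_ij^2 / sigma_i^2)`` with ``sigma_i`` the distance
        from cell i to its ceil(k/2)-th neighbor, symmetrized by maximum.
    umap_fuzzy_union
        Per-cell local scaling ``exp(-(d - rho_i) / sigma_i)`` with
        ``rho_i`` the nearest-neighbor distance and ``sigma_i`` calibrated
        so the smoothed degree is log2(deg); fuzzy union a+b-ab.

    Both are interpretations of "connectivity from cell-to-cell
    distances"; neither is canonical. The result is an undirected graph.
    """
    src_s, dst_s, dist_s, w = directed_kernel_weights(g, mode)
    n = g.n_cells

    if mode == "gaussian_adaptive":
        return _symmetrize_max(n, src_s, dst_s, w, dist_s)
    # fuzzy union: a + b - ab over the directed pair
    key: dict[tuple[int, int], tuple[float, float]] = {}
    for s, d, ww, dd in zip(src_s, dst_s, w, dist_s):
        a, b = (int(s), int(d)) if s < d else (int(d), int(s))
        prev = key.get((a, b))
        if prev is None:
            key[(a, b)] = (ww, dd)
        else:
            pw, pd = prev
            key[(a, b)] = (pw + ww - pw * ww, pd)
    m = len(key)
    out_src = np.empty(2 * m, dtype=np.int64)
    out_dst = np.empty(2 * m, dtype=np.int64)
    out_w = np.empty(2 * m)
    out_d = np.empty(2 * m)
    for e, ((a, b), (ww, dd)) in enumerate(sorted(key.items())):
        out_src[2 * e], out_dst[2 * e] = a, b
        out_src[2 * e + 1], out_dst[2 * e + 1] = b, a
        out_w[2 * e] = out_w[2 * e + 1] = ww
        out_d[2 * e] = out_d[2 * e + 1] = dd
    return NeighborGraph(n, g.k, out_src, out_dst, out_d, conn=out_w, directed=False)


def directed_kernel_weights(
    g: NeighborGraph, mode: str = "gaussian_adaptive"
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-edge directed connectivity weights, before symmetrization.

    Returns (src, dst, dist, weight) with edges grouped by source and
    sorted by (distance, index) within each source. For the
    gaussian_adaptive kernel the weights are monotone non-increasing in
    distance for each fixed source cell.
    """
    if g.n_edges == 0:
        raise ValueError("graph has no edges/distances")
    n = g.n_cells
    order = np.lexsort((g.dst, g.dist, g.src))
    src_s, dst_s, dist_s = g.src[order], g.dst[order], g.dist[order]
    starts = np.searchsorted(src_s, np.arange(n))
    ends = np.searchsorted(src_s, np.arange(n) + 1)

    w = np.empty_like(dist_s)
    if mode == "gaussian_adaptive":
        for i in range(n):
            lo, hi = starts[i], ends[i]
            if lo == hi:
                continue
            d = dist_s[lo:hi]
            deg = hi - lo
            kk = max(int(np.ceil(deg / 2)), 1)
            sigma = d[kk - 1]
            if sigma <= 0:
                pos = d[d > 0]
                sigma = pos.min() if len(pos) else 1.0
            w[lo:hi] = np.exp(-(d**2) / sigma**2)
    elif mode == "umap_fuzzy_union":
        for i in range(n):
            lo, hi = starts[i], ends[i]
            if lo == hi:
                continue
            d = dist_s[lo:hi]
            deg = hi - lo
            rho = d[0]
            target = np.log2(deg) if deg > 1 else 1.0
            d_adj = np.maximum(d - rho, 0.0)
            if np.all(d_adj == 0):
                w[lo:hi] = 1.0
                continue
            lo_s, hi_s = 1e-12, 1e12
            for _ in range(64):
                mid = np.sqrt(lo_s * hi_s)
                val = np.exp(-d_adj / mid).sum()
                if abs(val - target) < 1e-9:
                    break
                if val > target:
                    hi_s = mid
                else:
                    lo_s = mid
            w[lo:hi] = np.exp(-d_adj / mid)
    else:
        raise ValueError(f"unknown connectivity mode {mode!r}")

    w = np.clip(w, 1e-300, 1.0)
    return src_s, dst_s, dist_s, w


def connected_components(g: NeighborGraph, cell_mask: np.ndarray) -> np.ndarray:
    """Component label for every masked cell, treating edges as
    undirected and ignoring edges that leave the mask.

    Returns an int array of length ``mask.sum()`` with labels 0..n_comp-1
    (order of first appearance along the masked cell order).
    """
    mask = np.asarray(cell_mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("cell_mask selects no cells")
    sel = np.flatnonzero(mask)
    pos = -np.ones(g.n_cells, dtype=np.int64)
    pos[sel] = np.arange(len(sel))
    keep = mask[g.src] & mask[g.dst]
    sub = sp.csr_matrix(
        (np.ones(keep.sum()), (pos[g.src[keep]], pos[g.dst[keep]])),
        shape=(len(sel), len(sel)),
    )
    _, labels = _cc(sub, directed=False)
    # renumber by first appearance for determinism
    remap: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in remap:
            remap[lab] = len(remap)
        out[i] = remap[lab]
    return out
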