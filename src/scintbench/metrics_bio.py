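"""Biological-conservation metrics.

These ask whether an integration preserved biological structure:
cell-type purity of neighborhoods (cLISI), agreement between clusterings
and annotations (NMI/ARI), compactness/separation of cell types
(cell-type ASW), connectedness of each cell type in the kNN graph
(graph connectivity), preservation of between-cell-type geometry
(scGraph) and of the cell-cycle signal (cell-cycle conservation).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import spearmanr

from ._pcr import pc_scores, variance_weighted_r2
from .datamodel import CellDataset, MetricResult
from .metrics_batch import lisi_per_cell
from .neighbors import NeighborGraph, connected_components

__all__ = [
    "clisi",
    "nmi",
    "ari",
    "cluster_for_labels",
    "celltype_asw",
    "graph_connectivity",
    "scgraph",
    "score_gene_set",
    "cell_cycle_conservation",
    "CellCycleScores",
    "S_GENES_DEFAULT",
    "G2M_GENES_DEFAULT",
]

# Canonical human cell-cycle phase marker symbols (Tirosh-style lists),
# bundled as a convenience default; real analyses should pass sets
# matched to their organism and annotation.
S_GENES_DEFAULT = [
    "MCM5", "PCNA", "TYMS", "FEN1", "MCM2", "MCM4", "RRM1", "UNG", "GINS2",
    "MCM6", "CDCA7", "DTL", "PRIM1", "UHRF1", "HELLS", "RFC2", "RPA2",
    "NASP", "RAD51AP1", "GMNN", "WDR76", "SLBP", "CCNE2", "UBR7", "POLD3",
    "MSH2", "ATAD2", "RAD51", "RRM2", "CDC45", "CDC6", "EXO1", "TIPIN",
    "DSCC1", "BLM", "CASP8AP2", "USP1", "CLSPN", "POLA1", "CHAF1B",
    "BRIP1", "E2F8",
]
G2M_GENES_DEFAULT = [
    "HMGB2", "CDK1", "NUSAP1", "UBE2C", "BIRC5", "TPX2", "TOP2A", "NDC80",
    "CKS2", "NUF2", "CKS1B", "MKI67", "TMPO", "CENPF", "TACC3", "SMC4",
    "CCNB2", "CKAP2L", "CKAP2", "AURKB", "BUB1", "KIF11", "ANP32E",
    "TUBB4B", "GTSE1", "KIF20B", "HJURP", "CDCA3", "CDC20", "TTK",
    "CDC25C", "KIF2C", "RANGAP1", "NCAPD2", "DLGAP5", "CDCA2", "CDCA8",
    "ECT2", "KIF23", "HMMR", "AURKA", "PSRC1", "ANLN", "LBR", "CKAP5",
    "CENPE", "CTCF", "NEK2", "G2E3", "GAS2L3", "CBX5", "CENPA",
]


# ----------------------------------------------------------------------
# cLISI
# ----------------------------------------------------------------------

def clisi(g_or_embedding, celltype_labels, perplexity: float = 30.0
          ) -> MetricResult:
    """Cell-type LISI: neighborhood purity of cell-type labels.

    Raw value in [1, C]; scaled (C - mean) / (C - 1) is 1 when every
    neighborhood is pure and 0 under uniform mixing of all C types.
    """
    labels = np.asarray(celltype_labels)
    C = len(np.unique(labels))
    if C < 2:
        warnings.warn("cLISI with a single cell type is trivially pure")
        return MetricResult("clisi", 1.0, 1.0, params={"perplexity": perplexity})
    per_cell = lisi_per_cell(g_or_embedding, labels, perplexity)
    raw = float(per_cell.mean())
    scaled = float(np.clip((C - raw) / (C - 1.0), 0.0, 1.0))
    return MetricResult("clisi", raw, scaled, per_cell,
                        {"perplexity": perplexity, "n_labels": C})


# ----------------------------------------------------------------------
# NMI / ARI
# ----------------------------------------------------------------------

def nmi(a, b) -> MetricResult:
    """Normalized mutual information of two partitions (arithmetic-mean
    normalization). Single-cluster vs single-cluster is 1 by convention."""
    from sklearn.metrics import normalized_mutual_info_score

    a = np.asarray(a)
    b = np.asarray(b)
    if len(a) != len(b):
        raise ValueError("partitions must cover the same cells")
    if len(np.unique(a)) == 1 and len(np.unique(b)) == 1:
        v = 1.0
    else:
        v = float(normalized_mutual_info_score(a, b, average_method="arithmetic"))
    return MetricResult("nmi", v, v)


def ari(a, b) -> MetricResult:
    """Adjusted Rand index of two partitions, clamped to [0, 1] for the
    stored value (chance-level or worse scores 0); raw keeps the signed
    index in (-1, 1]."""
    from sklearn.metrics import adjusted_rand_score

    a = np.asarray(a)
    b = np.asarray(b)
    if len(a) != len(b):
        raise ValueError("partitions must cover the same cells")
    raw = float(adjusted_rand_score(a, b))
    return MetricResult("ari", raw, float(np.clip(raw, 0.0, 1.0)))


def cluster_for_labels(g: NeighborGraph, celltype_labels,
                       resolutions=(0.25, 0.5, 1.0, 2.0), seed: int = 0
                       ) -> np.ndarray:
    """Leiden partition of the connectivity graph that best matches the
    cell-type labels.

    Runs modularity-based (RBConfiguration) Leiden at each resolution on
    edge connectivities and returns the partition with the highest NMI
    against ``celltype_labels``. Seeded, hence deterministic.
    """
    import igraph as ig
    import leidenalg

    resolutions = list(resolutions)
    if not resolutions:
        raise ValueError("resolutions list is empty")
    if g.conn is None:
        raise ValueError("graph needs connectivities; run "
                         "connectivities_from_distances first")
    mask = g.src < g.dst  # undirected edge list, one record per pair
    edges = list(zip(g.src[mask].tolist(), g.dst[mask].tolist()))
    weights = g.conn[mask].tolist()
    graph = ig.Graph(n=g.n_cells, edges=edges)
    best, best_nmi = None, -1.0
    for res in resolutions:
        part = leidenalg.find_partition(
            graph,
            leidenalg.RBConfigurationVertexPartition,
            weights=weights,
            resolution_parameter=res,
            seed=seed,
            n_iterations=2,
        )
        labels = np.asarray(part.membership)
        score = nmi(labels, np.asarray(celltype_labels)).value
        if score > best_nmi:
            best, best_nmi = labels, score
    return best


# ----------------------------------------------------------------------
# cell-type ASW
# ----------------------------------------------------------------------

def celltype_asw(embedding: np.ndarray, celltype_labels) -> MetricResult:
    """Mean silhouette width with cell types as clusters, rescaled to
    [0, 1] via (ASW + 1) / 2."""
    from sklearn.metrics import silhouette_samples

    X = np.asarray(embedding, dtype=np.float64)
    labels = np.asarray(celltype_labels)
    if len(np.unique(labels)) < 2:
        return MetricResult("asw_celltype", np.nan, np.nan)
    s = silhouette_samples(X, labels)
    raw = float(s.mean())
    return MetricResult("asw_celltype", raw, (raw + 1.0) / 2.0, s)


# ----------------------------------------------------------------------
# graph connectivity
# ----------------------------------------------------------------------

def graph_connectivity(g: NeighborGraph, celltype_labels) -> MetricResult:
    """Mean, over cell types, of the fraction of that type's cells lying
    in the largest connected component of the type-induced subgraph.
    1 iff every label-induced subgraph is connected."""
    labels = np.asarray(celltype_labels)
    fracs = []
    for c in np.unique(labels):
        mask = labels == c
        comp = connected_components(g, mask)
        largest = np.bincount(comp).max()
        fracs.append(largest / mask.sum())
    raw = float(np.mean(fracs))
    return MetricResult("graph_connectivity", raw, raw, np.asarray(fracs))


# ----------------------------------------------------------------------
# scGraph
# ----------------------------------------------------------------------

def scgraph(embedding_reference: np.ndarray, embedding_integrated: np.ndarray,
            celltype_labels, batch_labels) -> MetricResult:
    """Preservation of between-cell-type centroid distances within batches.

    Per batch containing >= 3 cell types, the Spearman rank correlation
    between the pairwise type-centroid distance vectors of the reference
    and integrated spaces; raw = mean correlation, scaled = (raw + 1)/2.
    Missing when no batch has >= 3 types.
    """
    ref = np.asarray(embedding_reference, dtype=np.float64)
    intg = np.asarray(embedding_integrated, dtype=np.float64)
    ct = np.asarray(celltype_labels)
    batch = np.asarray(batch_labels)
    rhos = []
    for b in np.unique(batch):
        m = batch == b
        types = np.unique(ct[m])
        if len(types) < 3:
            continue
        cen_ref = np.stack([ref[m & (ct == t)].mean(axis=0) for t in types])
        cen_int = np.stack([intg[m & (ct == t)].mean(axis=0) for t in types])
        rho = spearmanr(pdist(cen_ref), pdist(cen_int)).statistic
        if np.isfinite(rho):
            rhos.append(float(rho))
    if not rhos:
        return MetricResult("scgraph", np.nan, np.nan)
    raw = float(np.mean(rhos))
    return MetricResult("scgraph", raw, float(np.clip((raw + 1.0) / 2.0, 0, 1)),
                        np.asarray(rhos), {"n_batches": len(rhos)})


# ----------------------------------------------------------------------
# cell-cycle conservation
# ----------------------------------------------------------------------

class CellCycleScores:
    """Per-cell S-phase and G2M-phase module scores."""

    def __init__(self, s: np.ndarray, g2m: np.ndarray,
                 s_genes: list, g2m_genes: list) -> None:
        if len(s) != len(g2m):
            raise ValueError("S and G2M scores must cover the same cells")
        if not len(s_genes) or not len(g2m_genes):
            raise ValueError("gene sets must be non-empty")
        self.s = np.asarray(s, dtype=np.float64)
        self.g2m = np.asarray(g2m, dtype=np.float64)
        self.s_genes = list(s_genes)
        self.g2m_genes = list(g2m_genes)

    def as_covariates(self) -> np.ndarray:
        return np.column_stack([self.s, self.g2m])


def _resolve_genes(ds: CellDataset, gene_set) -> np.ndarray:
    """Gene names or integer indices -> integer indices."""
    gene_set = list(gene_set)
    if all(isinstance(g, (int, np.integer)) for g in gene_set):
        return np.asarray(gene_set, dtype=np.int64)
    if ds.gene_names is None:
        raise ValueError("dataset has no gene names; pass integer indices")
    name_to_idx = {g: i for i, g in enumerate(ds.gene_names)}
    idx = [name_to_idx[g] for g in gene_set if g in name_to_idx]
    if not idx:
        raise ValueError("no gene-set member found in the dataset")
    return np.asarray(idx, dtype=np.int64)


def score_gene_set(ds: CellDataset, layer: str, gene_set, n_bins: int = 25,
                   n_ctrl: int = 50, seed: int = 0) -> np.ndarray:
    """Module score: per-cell mean expression of the set minus the mean
    of expression-matched control genes.

    Genes are binned into ``n_bins`` groups by mean expression; for each
    set gene, ``n_ctrl`` control genes are drawn (seeded, without
    replacement where possible) from the same bin, excluding set members.
    """
    X = ds.layer_dense(layer).astype(np.float64)
    idx = _resolve_genes(ds, gene_set)
    rng = np.random.default_rng(seed)
    gene_means = X.mean(axis=0)
    order = np.argsort(gene_means, kind="stable")
    bins = np.empty(len(gene_means), dtype=np.int64)
    bins[order] = np.arange(len(gene_means)) * n_bins // len(gene_means)
    in_set = np.zeros(len(gene_means), dtype=bool)
    in_set[idx] = True
    ctrl: list[int] = []
    for g in idx:
        pool = np.flatnonzero((bins == bins[g]) & ~in_set)
        if len(pool) == 0:
            continue
        take = min(n_ctrl, len(pool))
        ctrl.extend(rng.choice(pool, size=take, replace=False).tolist())
    if not ctrl:
        raise ValueError("no control genes available for the gene set")
    ctrl_idx = np.unique(ctrl)
    return X[:, idx].mean(axis=1) - X[:, ctrl_idx].mean(axis=1)


def cell_cycle_conservation(
    ds: CellDataset,
    X_before: np.ndarray,
    X_after: np.ndarray,
    s_genes=None,
    g2m_genes=None,
    n_pcs: int = 50,
    layer: str | None = None,
    seed: int = 0,
) -> MetricResult:
    """How well integration preserved the cell-cycle signal.

    S and G2M module scores are computed once from the expression layer.
    Per batch, the variance these two covariates explain in the
    pre-integration space (V_before) and post-integration space (V_after)
    is measured with the variance-weighted PC-regression construction;
    the per-batch score 1 - |V_after - V_before| / V_before (clamped to
    [0, 1]) is averaged over batches. Batches with V_before = 0 are
    skipped with a warning.
    """
    if layer is None:
        layer = "data" if "data" in ds.layers else next(iter(ds.layers))
    s_genes = s_genes if s_genes is not None else S_GENES_DEFAULT
    g2m_genes = g2m_genes if g2m_genes is not None else G2M_GENES_DEFAULT
    cc = CellCycleScores(
        score_gene_set(ds, layer, s_genes, seed=seed),
        score_gene_set(ds, layer, g2m_genes, seed=seed + 1),
        list(s_genes), list(g2m_genes),
    )
    cov = cc.as_covariates()
    Xb = np.asarray(X_before, dtype=np.float64)
    Xa = np.asarray(X_after, dtype=np.float64)
    batch = ds.batch_codes()
    per_batch = []
    for b in np.unique(batch):
        m = batch == b
        sb, vb = pc_scores(Xb[m], n_pcs)
        sa, va = pc_scores(Xa[m], n_pcs)
        V_before = variance_weighted_r2(sb, vb, cov[m])
        V_after = variance_weighted_r2(sa, va, cov[m])
        if V_before <= 0:
            warnings.warn(f"batch {b}: no cell-cycle variance before "
                          "integration; skipped")
            continue
        per_batch.append(float(np.clip(
            1.0 - abs(V_after - V_before) / V_before, 0.0, 1.0)))
    if not per_batch:
        return MetricResult("cc_conservation", np.nan, np.nan)
    raw = float(np.mean(per_batch))
    result = MetricResult("cc_conservation", raw, raw, np.asarray(per_batch),
                          {"n_pcs": n_pcs})
    result.scores = cc  # type: ignore[attr-defined]
    return result
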