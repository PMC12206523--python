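"""End-to-end scoring pipeline.

Given a reference dataset (with batch and cell-type labels and an
unintegrated embedding) and a set of integration outputs, compute every
applicable metric per method — including an "unintegrated" row — and
assemble a :class:`~scintbench.datamodel.ScoreTable` ready for
aggregation and plotting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._pcr import pc_scores
from .aggregate import metric_applicability
from .datamodel import CellDataset, IntegrationOutput, METRIC_REGISTRY, ScoreTable
from .metrics_batch import batch_asw, dpca, kbet, lisi, pcr_comparison
from .metrics_bio import (
    ari,
    cell_cycle_conservation,
    celltype_asw,
    clisi,
    cluster_for_labels,
    graph_connectivity,
    nmi,
    scgraph,
)
from .neighbors import NeighborGraph, connectivities_from_distances, knn_graph

__all__ = ["ScoringParams", "score_output", "score_methods", "DEFAULT_METRICS"]

DEFAULT_METRICS = [
    "ilisi", "kbet", "pcr", "dpca", "asw_batch",
    "clisi", "nmi", "ari", "asw_celltype", "graph_connectivity", "scgraph",
]


@dataclass
class ScoringParams:
    """Knobs shared by all metrics in one scoring run."""

    k: int = 15                 # kNN graph size for graph-based metrics
    perplexity: float = 30.0    # LISI neighborhood calibration
    alpha: float = 0.05         # kBET test level
    n_pcs: int = 20             # PCA depth for PCR/DPCA/cc-conservation
    resolutions: tuple = (0.25, 0.5, 1.0, 2.0)
    seed: int = 0
    s_genes: list | None = None     # enable cc_conservation when set
    g2m_genes: list | None = None


def _embedding_of(output: IntegrationOutput, n_pcs: int) -> np.ndarray | None:
    if output.kind == "embedding":
        return np.asarray(output.payload, dtype=np.float64)
    if output.kind == "matrix":
        scores, _ = pc_scores(np.asarray(output.payload), n_pcs)
        return scores
    return None


def _graph_of(output: IntegrationOutput, emb: np.ndarray | None, k: int
              ) -> NeighborGraph:
    if output.kind == "graph":
        return output.payload
    return knn_graph(emb, k)


def score_output(
    ds: CellDataset,
    output: IntegrationOutput,
    reference_embedding: np.ndarray,
    params: ScoringParams | None = None,
    metrics: list[str] | None = None,
) -> dict[str, float]:
    """All applicable metric values (oriented, in [0, 1]) for one method.

    Metrics that the output kind cannot support (PCA/silhouette scores
    for a graph) are simply absent from the result, as are metrics whose
    preconditions fail (e.g. scGraph with < 3 cell types per batch).
    """
    p = params or ScoringParams()
    metrics = list(metrics or DEFAULT_METRICS)
    batch = np.asarray(ds.batch)
    ct = np.asarray(ds.celltype) if ds.celltype is not None else None

    emb = _embedding_of(output, p.n_pcs)
    graph = _graph_of(output, emb, min(p.k, ds.n_cells - 1))
    lisi_input = emb if emb is not None else graph

    out: dict[str, float] = {}

    def want(m: str) -> bool:
        return m in metrics and metric_applicability(output, m)

    if want("ilisi"):
        out["ilisi"] = lisi(lisi_input, batch, p.perplexity).value
    if want("kbet"):
        out["kbet"] = kbet(graph, batch, p.alpha).value
    if want("pcr"):
        out["pcr"] = pcr_comparison(reference_embedding, emb, batch, p.n_pcs).value
    if want("dpca"):
        scores, var = pc_scores(emb, p.n_pcs)
        out["dpca"] = dpca(scores, batch, var).value
    if ct is not None:
        if want("asw_batch"):
            v = batch_asw(emb, batch, ct).value
            if np.isfinite(v):
                out["asw_batch"] = v
        if want("clisi"):
            out["clisi"] = clisi(lisi_input, ct, p.perplexity).value
        if want("nmi") or want("ari"):
            cg = graph
            if cg.conn is None:
                cg = connectivities_from_distances(cg)
            partition = cluster_for_labels(cg, ct, p.resolutions, p.seed)
            if want("nmi"):
                out["nmi"] = nmi(partition, ct).value
            if want("ari"):
                out["ari"] = ari(partition, ct).value
        if want("asw_celltype"):
            v = celltype_asw(emb, ct).value
            if np.isfinite(v):
                out["asw_celltype"] = v
        if want("graph_connectivity"):
            out["graph_connectivity"] = graph_connectivity(graph, ct).value
        if want("scgraph"):
            v = scgraph(reference_embedding, emb, ct, batch).value
            if np.isfinite(v):
                out["scgraph"] = v
        if want("cc_conservation") and p.s_genes and p.g2m_genes:
            v = cell_cycle_conservation(
                ds, reference_embedding, emb,
                p.s_genes, p.g2m_genes, p.n_pcs, seed=p.seed,
            ).value
            if np.isfinite(v):
                out["cc_conservation"] = v
    return out


def score_methods(
    ds: CellDataset,
    outputs: list[IntegrationOutput],
    reference_embedding: np.ndarray | None = None,
    params: ScoringParams | None = None,
    metrics: list[str] | None = None,
    include_unintegrated: bool = True,
) -> ScoreTable:
    """Score every integration output plus the unintegrated reference."""
    p = params or ScoringParams()
    if reference_embedding is None:
        if "latent_true" in ds.embeddings:
            reference_embedding = ds.embeddings["latent_true"]
        else:
            layer = "data" if "data" in ds.layers else next(iter(ds.layers))
            reference_embedding, _ = pc_scores(ds.layer_dense(layer), p.n_pcs)
    use_metrics = list(metrics or DEFAULT_METRICS)
    if p.s_genes and p.g2m_genes and "cc_conservation" not in use_metrics:
        use_metrics.append("cc_conservation")
    table = ScoreTable(
        methods=[],
        metrics=use_metrics,
        raw=np.empty((0, len(use_metrics))),
        category={m: METRIC_REGISTRY[m][0] for m in use_metrics},
        orientation={m: METRIC_REGISTRY[m][1] for m in use_metrics},
    )
    todo = list(outputs)
    if include_unintegrated:
        todo.insert(0, IntegrationOutput(
            "unintegrated", "embedding", np.asarray(reference_embedding)))
    for output in todo:
        table.add_method(
            output.method_name,
            score_output(ds, output, reference_embedding, p, use_metrics),
        )
    return table
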