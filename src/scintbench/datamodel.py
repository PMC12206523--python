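"""Core containers: expression bundles, integration outputs, score tables.

A :class:`CellDataset` bundles cells x genes layers with per-cell batch
(and optional cell-type) labels, named embeddings and named neighbor
graphs. Labels are case-sensitive and order-preserving as first
encountered. All components must agree on cell count and ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .neighbors import NeighborGraph

__all__ = [
    "CellDataset",
    "IntegrationOutput",
    "ScoreTable",
    "MetricResult",
    "DimensionError",
    "SchemaError",
]


class DimensionError(ValueError):
    """Component shapes disagree on cell or gene count."""


class SchemaError(ValueError):
    """A required column/field is absent or malformed."""


def _as_category(values, name: str) -> pd.Categorical:
    """Categorical with levels in order of first appearance, case-sensitive."""
    arr = np.asarray(values)
    if arr.ndim != 1:
        raise SchemaError(f"{name} labels must be 1-D")
    seen: dict = {}
    for v in arr:
        if v not in seen:
            seen[v] = None
    return pd.Categorical(arr, categories=list(seen))


@dataclass
class CellDataset:
    """Cells x genes expression layers plus annotations.

    layers hold at least one of "counts" (non-negative integers) or
    "data" (normalized reals); all layers share one (n_cells, n_genes)
    shape. ``batch`` is required, ``celltype`` optional.
    """

    layers: dict[str, np.ndarray | sp.spmatrix]
    batch: pd.Categorical
    celltype: pd.Categorical | None = None
    embeddings: dict[str, np.ndarray] = field(default_factory=dict)
    graphs: dict[str, NeighborGraph] = field(default_factory=dict)
    var_features: np.ndarray | None = None
    barcodes: list[str] | None = None
    gene_names: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.layers:
            raise SchemaError("CellDataset needs at least one layer")
        if not isinstance(self.batch, pd.Categorical):
            self.batch = _as_category(self.batch, "batch")
        if self.celltype is not None and not isinstance(self.celltype, pd.Categorical):
            self.celltype = _as_category(self.celltype, "celltype")
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        shapes = {name: lay.shape for name, lay in self.layers.items()}
        n_cells, n_genes = next(iter(shapes.values()))
        for name, shape in shapes.items():
            if shape != (n_cells, n_genes):
                raise DimensionError(
                    f"layer {name!r} has shape {shape}, expected {(n_cells, n_genes)}"
                )
        if len(self.batch) != n_cells:
            raise DimensionError(
                f"batch labels cover {len(self.batch)} cells, matrix has {n_cells}"
            )
        if len(self.batch.categories) < 1:
            raise SchemaError("batch must have at least one level")
        if self.celltype is not None and len(self.celltype) != n_cells:
            raise DimensionError("celltype labels disagree with cell count")
        for name, emb in self.embeddings.items():
            if emb.shape[0] != n_cells:
                raise DimensionError(
                    f"embedding {name!r} has {emb.shape[0]} rows, expected {n_cells}"
                )
        for name, g in self.graphs.items():
            if g.n_cells != n_cells:
                raise DimensionError(
                    f"graph {name!r} has {g.n_cells} cells, expected {n_cells}"
                )
        if self.var_features is not None and len(self.var_features) != n_genes:
            raise DimensionError("var_features flag disagrees with gene count")
        if "counts" in self.layers:
            c = self.layers["counts"]
            mn = c.min() if not sp.issparse(c) else c.data.min(initial=0)
            if mn < 0:
                raise SchemaError("counts layer has negative entries")
        if self.barcodes is not None and len(self.barcodes) != n_cells:
            raise DimensionError("barcodes disagree with cell count")
        if self.gene_names is not None and len(self.gene_names) != n_genes:
            raise DimensionError("gene names disagree with gene count")

    # -- basic properties -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return next(iter(self.layers.values())).shape[0]

    @property
    def n_genes(self) -> int:
        return next(iter(self.layers.values())).shape[1]

    def layer_dense(self, name: str) -> np.ndarray:
        lay = self.layers[name]
        return lay.toarray() if sp.issparse(lay) else np.asarray(lay)

    def batch_codes(self) -> np.ndarray:
        return np.asarray(self.batch.codes)

    def celltype_codes(self) -> np.ndarray:
        if self.celltype is None:
            raise SchemaError("dataset has no cell-type labels")
        return np.asarray(self.celltype.codes)


@dataclass
class IntegrationOutput:
    """One integration method's result, tagged with its output kind.

    kind determines which metrics are applicable downstream: a graph
    output has no numerical components, so PCA-based and silhouette-based
    scores cannot be computed for it.
    """

    method_name: str
    kind: str  # matrix | embedding | graph
    payload: np.ndarray | NeighborGraph

    _KINDS = ("matrix", "embedding", "graph")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}, got {self.kind!r}")
        if self.kind == "graph" and not isinstance(self.payload, NeighborGraph):
            raise ValueError("graph output payload must be a NeighborGraph")
        if self.kind in ("matrix", "embedding") and isinstance(
            self.payload, NeighborGraph
        ):
            raise ValueError(f"{self.kind} output payload cannot be a NeighborGraph")

    @property
    def n_cells(self) -> int:
        if isinstance(self.payload, NeighborGraph):
            return self.payload.n_cells
        return self.payload.shape[0]


@dataclass
class MetricResult:
    """A single metric evaluation with provenance.

    ``value`` is the oriented score actually entered into score tables
    (uniformly higher-is-better); ``raw`` keeps the metric's native
    quantity (e.g. mean LISI in [1, B], kBET rejection rate).
    """

    name: str
    raw: float
    value: float
    detail: np.ndarray | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.value) and not (-1e-9 <= self.value <= 1 + 1e-9):
            raise ValueError(
                f"scaled metric value must lie in [0,1], got {self.value} for {self.name}"
            )


#: metric name -> (category, orientation of the *stored* value)
METRIC_REGISTRY: dict[str, tuple[str, str]] = {
    "ilisi": ("batch", "higher_better"),
    "kbet": ("batch", "higher_better"),  # stored as acceptance rate
    "pcr": ("batch", "higher_better"),  # stored as before/after comparison
    "dpca": ("batch", "higher_better"),
    "asw_batch": ("batch", "higher_better"),
    "clisi": ("bio", "higher_better"),
    "nmi": ("bio", "higher_better"),
    "ari": ("bio", "higher_better"),
    "asw_celltype": ("bio", "higher_better"),
    "graph_connectivity": ("bio", "higher_better"),
    "scgraph": ("bio", "higher_better"),
    "cc_conservation": ("bio", "higher_better"),
}


@dataclass
class ScoreTable:
    """methods x metrics array of raw scores with per-metric metadata.

    Missing entries (NaN) are first-class: a metric that is not
    applicable to a method's output kind is simply absent.
    """

    methods: list[str]
    metrics: list[str]
    raw: np.ndarray  # methods x metrics, NaN = missing
    category: dict[str, str]  # metric -> batch | bio
    orientation: dict[str, str]  # metric -> higher_better | lower_better

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=np.float64)
        if self.raw.shape != (len(self.methods), len(self.metrics)):
            raise DimensionError(
                f"score array shape {self.raw.shape} != "
                f"({len(self.methods)}, {len(self.metrics)})"
            )
        for m in self.metrics:
            if m not in self.category:
                raise SchemaError(f"metric {m!r} has no category")
            if self.category[m] not in ("batch", "bio"):
                raise SchemaError(f"metric {m!r} category must be batch|bio")
            if m not in self.orientation:
                raise SchemaError(f"metric {m!r} has no orientation")
            if self.orientation[m] not in ("higher_better", "lower_better"):
                raise SchemaError(f"bad orientation for metric {m!r}")

    @classmethod
    def empty(cls, metrics: list[str] | None = None) -> "ScoreTable":
        metrics = list(metrics or [])
        return cls(
            methods=[],
            metrics=metrics,
            raw=np.empty((0, len(metrics))),
            category={m: METRIC_REGISTRY[m][0] for m in metrics},
            orientation={m: METRIC_REGISTRY[m][1] for m in metrics},
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.raw, index=self.methods, columns=self.metrics)

    def add_method(self, method: str, scores: dict[str, float]) -> None:
        """Append a row; metrics absent from ``scores`` are missing."""
        row = np.full(len(self.metrics), np.nan)
        for m, v in scores.items():
            if m not in self.metrics:
                raise SchemaError(f"metric {m!r} not in table")
            row[self.metrics.index(m)] = v
        self.methods.append(method)
        self.raw = np.vstack([self.raw, row]) if self.raw.size else row[None, :]
        self.raw = self.raw.reshape(len(self.methods), len(self.metrics))

    def copy(self) -> "ScoreTable":
        return ScoreTable(
            list(self.methods),
            list(self.metrics),
            self.raw.copy(),
            dict(self.category),
            dict(self.orientation),
        )
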