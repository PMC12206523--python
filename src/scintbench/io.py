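"""Directory-bundle readers/writers.

A bundle is a plain-text directory:

    matrix.mtx            sparse layer (MatrixMarket), orientation per manifest
    layer_<name>.mtx      additional layers
    barcodes.tsv          one cell barcode per line
    features.tsv          one gene name per line (2nd column: var-feature flag)
    obs.tsv               per-cell table with a ``batch`` column, optional
                          ``celltype``
    manifest.json         layer names, matrix orientation, format version
    embeddings/<name>.csv first column barcode, remaining columns = dims
    graphs/<name>.csv     edge list: src, dst, distance[, connectivity]

Everything is diff-friendly and inspectable; no binary containers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .datamodel import (
    CellDataset,
    DimensionError,
    METRIC_REGISTRY,
    SchemaError,
    ScoreTable,
)
from .neighbors import NeighborGraph

__all__ = ["read_bundle", "write_bundle", "read_scores", "write_scores",
           "read_graph_csv", "write_graph_csv", "read_embedding_csv"]

_FORMAT_VERSION = 1


def write_bundle(ds: CellDataset, path: str | Path) -> None:
    """Write a CellDataset as a directory bundle (see module docstring)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    barcodes = ds.barcodes or [f"cell{i}" for i in range(ds.n_cells)]
    genes = ds.gene_names or [f"gene{j}" for j in range(ds.n_genes)]

    layer_names = list(ds.layers)
    manifest = {
        "format_version": _FORMAT_VERSION,
        "orientation": "cells_x_genes",
        "layers": layer_names,
        "primary_layer": layer_names[0],
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))

    for i, name in enumerate(layer_names):
        lay = ds.layers[name]
        mat = sp.coo_matrix(lay)
        target = path / ("matrix.mtx" if i == 0 else f"layer_{name}.mtx")
        mmwrite(str(target), mat)

    (path / "barcodes.tsv").write_text("\n".join(barcodes) + "\n")
    flags = (
        ds.var_features
        if ds.var_features is not None
        else np.zeros(ds.n_genes, dtype=bool)
    )
    with open(path / "features.tsv", "w") as fh:
        for g, f in zip(genes, flags):
            fh.write(f"{g}\t{int(f)}\n")

    obs = pd.DataFrame({"barcode": barcodes, "batch": np.asarray(ds.batch)})
    if ds.celltype is not None:
        obs["celltype"] = np.asarray(ds.celltype)
    obs.to_csv(path / "obs.tsv", sep="\t", index=False)

    if ds.embeddings:
        (path / "embeddings").mkdir(exist_ok=True)
        for name, emb in ds.embeddings.items():
            df = pd.DataFrame(
                emb, columns=[f"dim{j + 1}" for j in range(emb.shape[1])]
            )
            df.insert(0, "barcode", barcodes)
            df.to_csv(path / "embeddings" / f"{name}.csv", index=False)

    if ds.graphs:
        (path / "graphs").mkdir(exist_ok=True)
        for name, g in ds.graphs.items():
            write_graph_csv(g, path / "graphs" / f"{name}.csv")


def read_bundle(path: str | Path) -> CellDataset:
    """Read a directory bundle back into a CellDataset.

    Raises :class:`DimensionError` naming the offending file on shape
    mismatch, :class:`SchemaError` when the batch column is absent.
    """
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    orientation = manifest.get("orientation", "cells_x_genes")

    def load_mtx(p: Path) -> sp.csr_matrix:
        m = sp.csr_matrix(mmread(str(p)))
        return m.T.tocsr() if orientation == "genes_x_cells" else m

    layers: dict[str, sp.spmatrix] = {}
    primary = manifest.get("primary_layer", manifest["layers"][0])
    for name in manifest["layers"]:
        p = path / ("matrix.mtx" if name == primary else f"layer_{name}.mtx")
        layers[name] = load_mtx(p)

    barcodes = (path / "barcodes.tsv").read_text().strip("\n").split("\n")
    feats = pd.read_csv(
        path / "features.tsv", sep="\t", header=None, names=["gene", "flag"]
    )
    genes = feats["gene"].astype(str).tolist()
    var_features = feats["flag"].astype(bool).to_numpy()

    n_cells, n_genes = layers[primary].shape
    if len(barcodes) != n_cells:
        raise DimensionError(
            f"barcodes.tsv has {len(barcodes)} rows but matrix.mtx has {n_cells} cells"
        )
    if len(genes) != n_genes:
        raise DimensionError(
            f"features.tsv has {len(genes)} rows but matrix.mtx has {n_genes} genes"
        )

    obs = pd.read_csv(path / "obs.tsv", sep="\t", dtype=str)
    if "batch" not in obs.columns:
        raise SchemaError("obs.tsv lacks the required 'batch' column")
    if len(obs) != n_cells:
        raise DimensionError(
            f"obs.tsv has {len(obs)} rows but matrix.mtx has {n_cells} cells"
        )

    embeddings: dict[str, np.ndarray] = {}
    emb_dir = path / "embeddings"
    if emb_dir.is_dir():
        for f in sorted(emb_dir.glob("*.csv")):
            embeddings[f.stem] = read_embedding_csv(f, n_cells)

    graphs: dict[str, NeighborGraph] = {}
    graph_dir = path / "graphs"
    if graph_dir.is_dir():
        for f in sorted(graph_dir.glob("*.csv")):
            graphs[f.stem] = read_graph_csv(f, n_cells)

    celltype = obs["celltype"].to_numpy() if "celltype" in obs.columns else None
    return CellDataset(
        layers=layers,
        batch=obs["batch"].to_numpy(),
        celltype=celltype,
        embeddings=embeddings,
        graphs=graphs,
        var_features=var_features,
        barcodes=barcodes,
        gene_names=genes,
    )


def read_embedding_csv(path: str | Path, n_cells: int | None = None) -> np.ndarray:
    """Embedding CSV: header row, first column barcode, rest numeric dims."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: embedding CSV needs a barcode column plus dims")
    emb = df.iloc[:, 1:].to_numpy(dtype=np.float64)
    if n_cells is not None and emb.shape[0] != n_cells:
        raise DimensionError(
            f"{path}: embedding has {emb.shape[0]} rows, expected {n_cells}"
        )
    return emb


def write_graph_csv(g: NeighborGraph, path: str | Path) -> None:
    cols = {"src": g.src, "dst": g.dst, "distance": g.dist}
    if g.conn is not None:
        cols["connectivity"] = g.conn
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(f"# n_cells={g.n_cells} k={g.k} directed={int(g.directed)}\n")
        df.to_csv(fh, index=False)


def read_graph_csv(path: str | Path, n_cells: int | None = None) -> NeighborGraph:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise SchemaError(f"{path}: graph CSV lacks its metadata header line")
        meta = dict(tok.split("=") for tok in header[1:].split())
        df = pd.read_csv(fh)
    n = int(meta["n_cells"])
    if n_cells is not None and n != n_cells:
        raise DimensionError(f"{path}: graph covers {n} cells, expected {n_cells}")
    conn = df["connectivity"].to_numpy() if "connectivity" in df.columns else None
    return NeighborGraph(
        n_cells=n,
        k=int(meta["k"]),
        src=df["src"].to_numpy(),
        dst=df["dst"].to_numpy(),
        dist=df["distance"].to_numpy(),
        conn=conn,
        directed=bool(int(meta.get("directed", 1))),
    )


# -- score tables ---------------------------------------------------------

def write_scores(t: ScoreTable, path: str | Path, format: str = "csv") -> None:
    """Persist a score table; missing = empty CSV cell / JSON null."""
    path = Path(path)
    if format == "csv":
        df = t.to_frame()
        meta_cat = pd.DataFrame(
            [[t.category[m] for m in t.metrics]], index=["__category__"],
            columns=t.metrics,
        )
        meta_ori = pd.DataFrame(
            [[t.orientation[m] for m in t.metrics]], index=["__orientation__"],
            columns=t.metrics,
        )
        pd.concat([meta_cat, meta_ori, df]).to_csv(path, index_label="method")
    elif format == "json":
        obj = {
            "methods": t.methods,
            "metrics": t.metrics,
            "category": {m: t.category[m] for m in t.metrics},
            "orientation": {m: t.orientation[m] for m in t.metrics},
            "raw": [
                [None if np.isnan(v) else v for v in row] for row in t.raw
            ],
        }
        Path(path).write_text(json.dumps(obj, indent=1))
    else:
        raise ValueError(f"unknown score-table format {format!r}")


def read_scores(path: str | Path, format: str | None = None) -> ScoreTable:
    path = Path(path)
    if format is None:
        format = "json" if path.suffix == ".json" else "csv"
    if format == "csv":
        df = pd.read_csv(path, index_col=0)
        category = df.loc["__category__"].to_dict()
        orientation = df.loc["__orientation__"].to_dict()
        body = df.drop(index=["__category__", "__orientation__"]).astype(float)
        return ScoreTable(
            methods=list(body.index),
            metrics=list(body.columns),
            raw=body.to_numpy(),
            category=category,
            orientation=orientation,
        )
    if format == "json":
        obj = json.loads(Path(path).read_text())
        raw = np.array(
            [[np.nan if v is None else v for v in row] for row in obj["raw"]],
            dtype=np.float64,
        ).reshape(len(obj["methods"]), len(obj["metrics"]))
        return ScoreTable(
            methods=obj["methods"],
            metrics=obj["metrics"],
            raw=raw,
            category=obj["category"],
            orientation=obj["orientation"],
        )
    raise ValueError(f"unknown score-table format {format!r}")
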