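"""Score visualizations: dotplot, lollipop and radar plots.

All plots are deterministic (fixed method/metric ordering, no random
layout) and write SVG or PNG depending on the output suffix. Missing
score cells draw no dot, matching their first-class missing status in
the table.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .aggregate import CompositeScores, composite, rescale
from .datamodel import ScoreTable

__all__ = ["dotplot", "lollipop", "radar", "plot_scores"]


def _check(table: ScoreTable) -> None:
    if not table.methods or not table.metrics:
        raise ValueError("cannot plot an empty score table")


def dotplot(table: ScoreTable, path: str | Path,
            rescale_mode: str = "minmax_ranks") -> None:
    """methods x metrics grid; dot size and color encode the rescaled
    score, absent dots mark missing entries."""
    _check(table)
    scaled = rescale(table, rescale_mode) if rescale_mode != "none" else table
    n_m, n_s = len(table.methods), len(table.metrics)
    fig, ax = plt.subplots(figsize=(1.2 + 0.6 * n_s, 1.2 + 0.45 * n_m))
    for i in range(n_m):
        for j in range(n_s):
            v = scaled.raw[i, j]
            if np.isnan(v):
                continue
            ax.scatter(j, i, s=40 + 260 * v, c=[v], cmap="viridis",
                       vmin=0, vmax=1, edgecolors="k", linewidths=0.4)
    ax.set_xticks(range(n_s), table.metrics, rotation=45, ha="right")
    ax.set_yticks(range(n_m), table.methods)
    ax.invert_yaxis()
    cats = [table.category[m] for m in table.metrics]
    if "batch" in cats and "bio" in cats:
        split = cats.index("bio") if cats[0] == "batch" else cats.index("batch")
        ax.axvline(split - 0.5, color="grey", ls="--", lw=0.8)
    ax.set_xlim(-0.7, n_s - 0.3)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def lollipop(table: ScoreTable, path: str | Path, w_batch: float = 0.5,
             w_bio: float = 0.5, rescale_mode: str = "minmax_ranks") -> None:
    """Per-method composite scores as horizontal stems."""
    _check(table)
    cs = composite(table, w_batch, w_bio, rescale_mode)
    order = np.argsort(np.nan_to_num(cs.overall, nan=-1.0))
    fig, ax = plt.subplots(figsize=(6, 1.0 + 0.5 * len(cs.methods)))
    y = np.arange(len(cs.methods))
    for off, vals, color, label in (
        (-0.18, cs.batch_correction, "tab:blue", "batch correction"),
        (0.0, cs.bio_conservation, "tab:green", "bio conservation"),
        (0.18, cs.overall, "tab:red", "overall"),
    ):
        v = vals[order]
        ax.hlines(y + off, 0, np.nan_to_num(v), color=color, alpha=0.6)
        ax.plot(v, y + off, "o", color=color, label=label)
    ax.set_yticks(y, [cs.methods[i] for i in order])
    ax.set_xlabel("score")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def radar(table: ScoreTable, path: str | Path,
          rescale_mode: str = "minmax_ranks") -> None:
    """One polygon per method over the rescaled metrics."""
    _check(table)
    scaled = rescale(table, rescale_mode) if rescale_mode != "none" else table
    n_s = len(table.metrics)
    angles = np.linspace(0, 2 * np.pi, n_s, endpoint=False)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"},
                           figsize=(6.5, 6.5))
    for i, method in enumerate(table.methods):
        vals = np.nan_to_num(scaled.raw[i], nan=0.0)
        closed = np.concatenate([vals, vals[:1]])
        ang = np.concatenate([angles, angles[:1]])
        ax.plot(ang, closed, label=method)
        ax.fill(ang, closed, alpha=0.08)
    ax.set_xticks(angles, table.metrics, fontsize=8)
    ax.set_ylim(0, 1)
    ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.1), fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_scores(table: ScoreTable, kind: str, path: str | Path, **kw) -> None:
    """Dispatch on plot kind: dotplot | lollipop | radar."""
    kinds = {"dotplot": dotplot, "lollipop": lollipop, "radar": radar}
    if kind not in kinds:
        raise ValueError(f"unknown plot kind {kind!r}; choose from {sorted(kinds)}")
    kinds[kind](table, path, **kw)
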