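"""Score assembly: rescaling, composite scores, ranking, applicability.

Raw metric values are first oriented higher-is-better, then min-max
rescaled per metric — either on the scores directly or on average ranks
computed from them (the rank route is more stable against methods being
added or removed, since it is invariant to any strictly monotone
transform of a metric column). Category means give a batch-correction
and a bio-conservation composite; the overall score is their weighted
sum and drives the ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datamodel import IntegrationOutput, ScoreTable

__all__ = [
    "CompositeScores",
    "rescale",
    "composite",
    "overall_and_rank",
    "metric_applicability",
]


@dataclass
class CompositeScores:
    """Per-method composite scores and the weights that define them."""

    methods: list[str]
    batch_correction: np.ndarray
    bio_conservation: np.ndarray
    overall: np.ndarray
    w_batch: float = 0.5
    w_bio: float = 0.5
    rescale_mode: str = "minmax_ranks"

    def __post_init__(self) -> None:
        if self.w_batch < 0 or self.w_bio < 0:
            raise ValueError("weights must be non-negative")
        if abs(self.w_batch + self.w_bio - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        for name, v in (("batch", self.batch_correction),
                        ("bio", self.bio_conservation),
                        ("overall", self.overall)):
            if len(v) != len(self.methods):
                raise ValueError(f"{name} scores disagree with method count")
        expected = self.w_batch * self.batch_correction + self.w_bio * self.bio_conservation
        ok = np.isnan(self.overall) | np.isclose(self.overall, expected, equal_nan=True)
        if not np.all(ok | np.isnan(expected)):
            raise ValueError("overall != w_batch*batch + w_bio*bio")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "batch_correction": self.batch_correction,
                "bio_conservation": self.bio_conservation,
                "overall": self.overall,
            },
            index=self.methods,
        )


def _oriented(t: ScoreTable) -> np.ndarray:
    """Raw matrix with lower-better columns negated (higher = better)."""
    X = t.raw.copy()
    for j, m in enumerate(t.metrics):
        if t.orientation[m] == "lower_better":
            X[:, j] = -X[:, j]
    return X


def rescale(table: ScoreTable, mode: str = "minmax_ranks") -> ScoreTable:
    """Per-metric min-max rescaling of scores or of average ranks.

    Columns are oriented higher-better first. Constant columns map to
    0.5 everywhere; missing entries stay missing; a column with fewer
    than 2 observed values is left at 0.5 for the observed entry.
    """
    if mode not in ("minmax_scores", "minmax_ranks"):
        raise ValueError(f"unknown rescale mode {mode!r}")
    X = _oriented(table)
    out = np.full_like(X, np.nan)
    for j in range(X.shape[1]):
        col = X[:, j]
        obs = ~np.isnan(col)
        if obs.sum() == 0:
            continue
        vals = col[obs]
        if mode == "minmax_ranks":
            vals = rankdata(vals, method="average")
        lo, hi = vals.min(), vals.max()
        if hi - lo <= 0:
            out[obs, j] = 0.5
        else:
            out[obs, j] = (vals - lo) / (hi - lo)
    rescaled = table.copy()
    rescaled.raw = out
    # after rescaling every column is higher-better by construction
    rescaled.orientation = {m: "higher_better" for m in table.metrics}
    return rescaled


def composite(table: ScoreTable, w_batch: float = 0.5, w_bio: float = 0.5,
              rescale_mode: str = "minmax_ranks") -> CompositeScores:
    """Category means of the rescaled table plus the weighted overall.

    Each composite is the mean over that category's non-missing rescaled
    entries; a method with an entirely missing category gets a missing
    composite and a missing overall.
    """
    if rescale_mode == "none":
        scaled = table.copy()
        scaled.raw = _oriented(table)
    else:
        scaled = rescale(table, rescale_mode)
    cats = np.array([table.category[m] for m in table.metrics])
    n = len(table.methods)
    batch = np.full(n, np.nan)
    bio = np.full(n, np.nan)
    for i in range(n):
        for cat, dest in (("batch", batch), ("bio", bio)):
            vals = scaled.raw[i, cats == cat]
            vals = vals[~np.isnan(vals)]
            if len(vals):
                dest[i] = vals.mean()
    overall = w_batch * batch + w_bio * bio
    return CompositeScores(list(table.methods), batch, bio, overall,
                           w_batch, w_bio, rescale_mode)


def overall_and_rank(cs: CompositeScores) -> pd.DataFrame:
    """Methods ordered best-first by overall score.

    Ties on overall break by bio-conservation (descending), then method
    name (ascending). Missing overalls sort last. Adds a 1-based
    ``rank`` column.
    """
    order = sorted(
        range(len(cs.methods)),
        key=lambda i: (
            np.isnan(cs.overall[i]),
            -(cs.overall[i] if not np.isnan(cs.overall[i]) else -np.inf),
            -(cs.bio_conservation[i]
              if not np.isnan(cs.bio_conservation[i]) else -np.inf),
            cs.methods[i],
        ),
    )
    df = cs.to_frame().iloc[order].copy()
    df["rank"] = np.arange(1, len(order) + 1)
    return df


#: metrics that need numerical components (a matrix or embedding);
#: everything else works from a kNN graph, which can itself be derived
#: from an embedding or matrix when absent.
_NEEDS_COMPONENTS = frozenset(
    {"pcr", "pcr_raw", "dpca", "asw_batch", "asw_celltype", "scgraph",
     "cc_conservation"}
)


def metric_applicability(output: IntegrationOutput, metric: str) -> bool:
    """Whether a metric can be computed for an integration output kind.

    Graph outputs have no numerical components, so PCA- and
    silhouette-based scores are not computed for them; graph-based
    metrics apply to every kind (the graph is built from the embedding
    or matrix when needed).
    """
    if output.kind == "graph" and metric in _NEEDS_COMPONENTS:
        return False
    return True
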