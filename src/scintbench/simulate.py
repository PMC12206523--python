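"""Ground-truth synthetic data: cell types, batch effects, cell cycle.

The generator factorizes into a latent layer and a count layer. Cells
live in a d-dimensional latent space as a Gaussian mixture over cell
types; batch effects act as latent-space shift vectors plus per-gene
additive (log-scale) and multiplicative effects on the count means.
Counts are negative-binomial with log-normal library sizes. Because the
true latent coordinates are retained as an embedding, embedding-based
metrics can be tested without any dimensionality-reduction step, and
the exact batch shifts are available for oracle integrations.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datamodel import CellDataset

__all__ = ["SyntheticTruth", "simulate_latent", "simulate_counts", "preset",
           "oracle_integration"]


@dataclass
class SyntheticTruth:
    """Generator parameters; everything needed to reproduce a dataset.

    ``type_separation`` (s) is the RMS pairwise distance between type
    centroids; ``batch_shift`` (m) the Euclidean norm of each batch's
    latent shift; ``sigma`` the within-type latent SD. ``cells`` is a
    (n_batches, n_types) table of cells per batch and type.
    """

    name: str = "custom"
    n_batches: int = 2
    n_types: int = 5
    cells: np.ndarray | None = None  # (n_batches, n_types)
    latent_dim: int = 10
    sigma: float = 1.0
    type_separation: float = 6.0
    batch_shift: float = 0.0
    n_genes: int = 400
    nb_dispersion: float = 2.0
    lib_mu: float = 9.2  # log-normal location of library size (~1e4)
    lib_sigma: float = 0.25
    additive_sd: float = 0.3  # per-gene log-scale batch effect SD
    multiplicative_sd: float = 0.15
    cc_program: bool = False
    cc_strength: float = 1.0
    cc_set_size: int = 20
    seed: int = 0
    # nested design: batches grouped into studies; within-study shift norm
    study_of_batch: list[int] | None = None
    within_study_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.cells is None:
            self.cells = np.full((self.n_batches, self.n_types), 50, dtype=np.int64)
        self.cells = np.asarray(self.cells, dtype=np.int64)
        if self.cells.shape != (self.n_batches, self.n_types):
            raise ValueError("cells table must be (n_batches, n_types)")
        if np.any(self.cells < 0):
            raise ValueError("cell counts must be >= 0")
        if self.batch_shift < 0 or self.sigma <= 0 or self.nb_dispersion <= 0:
            raise ValueError("invalid scale parameter")

    @property
    def n_cells(self) -> int:
        return int(self.cells.sum())

    # -- derived deterministic parameters ------------------------------
    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, stream))

    def type_centroids(self) -> np.ndarray:
        """Centroids drawn once from an isotropic Gaussian, then scaled so
        the RMS pairwise distance equals ``type_separation``."""
        rng = self.rng(1)
        C = rng.standard_normal((self.n_types, self.latent_dim))
        C -= C.mean(axis=0, keepdims=True)
        if self.n_types > 1 and self.type_separation > 0:
            d2 = ((C[:, None] - C[None, :]) ** 2).sum(-1)
            rms = np.sqrt(d2[np.triu_indices(self.n_types, 1)].mean())
            C *= self.type_separation / rms
        else:
            C *= 0.0
        return C

    def batch_shifts(self) -> np.ndarray:
        """Per-batch latent shift vectors of norm ``batch_shift``; in the
        nested design, a study-level shift plus a within-study one."""
        rng = self.rng(2)
        def unit(v):
            n = np.linalg.norm(v)
            return v / n if n > 0 else v
        if self.study_of_batch is not None:
            studies = np.asarray(self.study_of_batch)
            study_vecs = {
                s: self.batch_shift * unit(rng.standard_normal(self.latent_dim))
                for s in np.unique(studies)
            }
            shifts = np.stack([
                study_vecs[s]
                + self.within_study_shift * unit(rng.standard_normal(self.latent_dim))
                for s in studies
            ])
            return shifts
        if self.batch_shift == 0:
            return np.zeros((self.n_batches, self.latent_dim))
        return np.stack([
            self.batch_shift * unit(rng.standard_normal(self.latent_dim))
            for _ in range(self.n_batches)
        ])

    def gene_loadings(self) -> np.ndarray:
        rng = self.rng(3)
        return rng.standard_normal((self.n_genes, self.latent_dim)) / np.sqrt(
            self.latent_dim
        )

    def gene_batch_effects(self) -> tuple[np.ndarray, np.ndarray]:
        """(additive log-scale offsets, multiplicative factors), each
        (n_batches, n_genes); zero-centered across batches."""
        rng = self.rng(4)
        add = rng.normal(0.0, self.additive_sd, (self.n_batches, self.n_genes))
        mult = np.exp(rng.normal(0.0, self.multiplicative_sd,
                                 (self.n_batches, self.n_genes)))
        add -= add.mean(axis=0, keepdims=True)
        return add, mult

    def cc_gene_sets(self) -> tuple[np.ndarray, np.ndarray]:
        """Indices of the designated S-phase and G2M-phase program genes
        (the last 2 * cc_set_size genes)."""
        k = self.cc_set_size
        s = np.arange(self.n_genes - 2 * k, self.n_genes - k)
        g2m = np.arange(self.n_genes - k, self.n_genes)
        return s, g2m

    # -- config round-trip ---------------------------------------------
    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["cells"] = self.cells.tolist()
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        d["cells"] = np.asarray(d["cells"], dtype=np.int64)
        return cls(**d)


def _labels(truth: SyntheticTruth) -> tuple[np.ndarray, np.ndarray]:
    batch = np.concatenate([
        np.full(truth.cells[b].sum(), b, dtype=np.int64)
        for b in range(truth.n_batches)
    ])
    ctype = np.concatenate([
        np.repeat(np.arange(truth.n_types), truth.cells[b])
        for b in range(truth.n_batches)
    ])
    return batch, ctype


def simulate_latent(truth: SyntheticTruth) -> CellDataset:
    """Latent Gaussian-mixture dataset with batch shifts.

    A cell of type t in batch b is drawn from
    Normal(centroid_t + shift_b, sigma^2 I). The dataset carries the
    observed embedding "latent_true", the unshifted (batch-effect-free)
    embedding "latent_clean", and a "latent" expression-free layer view
    for IO convenience.
    """
    rng = truth.rng(5)
    batch, ctype = _labels(truth)
    C = truth.type_centroids()
    S = truth.batch_shifts()
    noise = rng.standard_normal((truth.n_cells, truth.latent_dim)) * truth.sigma
    clean = C[ctype] + noise
    observed = clean + S[batch]
    phase = truth.rng(6).uniform(0.0, 2 * np.pi, truth.n_cells)
    ds = CellDataset(
        layers={"data": observed.copy()},
        batch=np.array([f"batch{b}" for b in batch]),
        celltype=np.array([f"type{t:02d}" for t in ctype]),
        embeddings={"latent_true": observed, "latent_clean": clean},
    )
    ds.cc_phase = phase  # type: ignore[attr-defined]
    return ds


def simulate_counts(truth: SyntheticTruth, latent: CellDataset | None = None
                    ) -> CellDataset:
    """Negative-binomial count layer on top of the latent dataset.

    Per-gene mean: exp(loadings . latent_observed + additive batch
    effect) scaled by the multiplicative batch effect and a log-normal
    library-size factor; counts ~ NB(mean, dispersion). The optional
    cell-cycle program adds sin/cos phase signal to the designated S and
    G2M gene sets on the log scale.
    """
    if latent is None:
        latent = simulate_latent(truth)
    rng = truth.rng(7)
    batch = latent.batch_codes()
    Z = latent.embeddings["latent_true"]
    W = truth.gene_loadings()
    add, mult = truth.gene_batch_effects()

    log_mu = Z @ W.T + add[batch]  # cells x genes
    if truth.cc_program:
        s_idx, g2m_idx = truth.cc_gene_sets()
        phase = getattr(latent, "cc_phase",
                        truth.rng(6).uniform(0, 2 * np.pi, truth.n_cells))
        s_sig = np.maximum(np.sin(phase), 0.0) * truth.cc_strength
        g2m_sig = np.maximum(np.cos(phase), 0.0) * truth.cc_strength
        log_mu[:, s_idx] += s_sig[:, None]
        log_mu[:, g2m_idx] += g2m_sig[:, None]

    # stabilize: center per gene and keep means in a realistic range
    log_mu = log_mu - log_mu.mean(axis=0, keepdims=True)
    log_mu = np.clip(log_mu, -8.0, 8.0)
    base = rng.normal(-1.0, 1.0, truth.n_genes)  # per-gene baseline abundance
    lib = rng.lognormal(truth.lib_mu, truth.lib_sigma, truth.n_cells)
    mu = np.exp(log_mu + base[None, :]) * mult[batch]
    mu = mu / mu.sum(axis=1, keepdims=True) * lib[:, None]

    theta = truth.nb_dispersion
    counts = rng.negative_binomial(theta, theta / (theta + mu))
    data = np.log1p(counts / counts.sum(axis=1, keepdims=True) * 1e4)

    ds = CellDataset(
        layers={"counts": counts.astype(np.int64), "data": data},
        batch=np.asarray(latent.batch),
        celltype=np.asarray(latent.celltype) if latent.celltype is not None else None,
        embeddings=dict(latent.embeddings),
        gene_names=[f"gene{j:04d}" for j in range(truth.n_genes)],
    )
    return ds


def oracle_integration(truth: SyntheticTruth, ds: CellDataset) -> np.ndarray:
    """Perfect integration of the latent embedding: subtract the true
    batch shifts. The benchmark's upper-bound reference."""
    shifts = truth.batch_shifts()
    return ds.embeddings["latent_true"] - shifts[ds.batch_codes()]


def preset(name: str, seed: int = 0) -> SyntheticTruth:
    """Named parameter bundles.

    well_mixed
        4 batches x 250 cells, 6 types, no batch effect (m = 0).
    shifted
        As well_mixed but with a strong latent batch shift (m = 6) and
        per-gene effects — the standard integration test bed.
    nested_atlas
        The atlas-style design: 4 studies x 2 samples x 1250 cells
        (10 000 cells total), 17 cell types, study-level shifts with
        smaller within-study sample shifts, cell-cycle program on.
    """
    if name == "well_mixed":
        return SyntheticTruth(
            name=name, n_batches=4, n_types=6,
            cells=_spread(250, 6, 4),
            batch_shift=0.0, seed=seed,
        )
    if name == "shifted":
        return SyntheticTruth(
            name=name, n_batches=4, n_types=6,
            cells=_spread(250, 6, 4),
            batch_shift=6.0, seed=seed,
        )
    if name == "nested_atlas":
        return SyntheticTruth(
            name=name, n_batches=8, n_types=17,
            cells=_spread(1250, 17, 8),
            batch_shift=6.0,
            study_of_batch=[0, 0, 1, 1, 2, 2, 3, 3],
            within_study_shift=2.0,
            n_genes=800,
            cc_program=True,
            seed=seed,
        )
    raise ValueError(f"unknown preset {name!r}")


def _spread(per_batch: int, n_types: int, n_batches: int) -> np.ndarray:
    """Cells-per-(batch,type) table summing to per_batch in every batch."""
    base = np.full(n_types, per_batch // n_types, dtype=np.int64)
    base[: per_batch % n_types] += 1
    return np.tile(base, (n_batches, 1))
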