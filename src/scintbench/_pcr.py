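"""Principal-component scores and variance-weighted regression R^2.

Shared machinery for the Regression-PCA, DPCA and cell-cycle
conservation metrics: PCA of an input matrix, then the fraction of
embedding variance linearly explained by a set of covariates, weighting
each PC's R^2 by that PC's variance.
"""

from __future__ import annotations

import numpy as np

__all__ = ["pc_scores", "variance_weighted_r2"]


def pc_scores(X: np.ndarray, n_pcs: int) -> tuple[np.ndarray, np.ndarray]:
    """Centered PCA scores and per-PC variances.

    Returns (scores (n, n_pcs), variances (n_pcs,)). Deterministic
    (full SVD; sign fixed by largest absolute loading).
    """
    X = np.asarray(X, dtype=np.float64)
    n, p = X.shape
    n_pcs = min(n_pcs, n - 1, p)
    if n_pcs < 1:
        raise ValueError("need at least one principal component")
    Xc = X - X.mean(axis=0, keepdims=True)
    if np.allclose(Xc, 0):
        raise ValueError("input matrix is constant; PCA undefined")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each PC positive
    for j in range(min(len(S), n_pcs)):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    scores = U[:, :n_pcs] * S[:n_pcs]
    var = (S[:n_pcs] ** 2) / (n - 1)
    return scores, var


def variance_weighted_r2(
    scores: np.ndarray, variances: np.ndarray, covariates: np.ndarray
) -> float:
    """Variance-weighted mean R^2 of per-PC least-squares regressions.

    Each PC's scores are regressed on the covariate matrix (an intercept
    is added); the per-PC coefficients of determination are averaged with
    the PC variances as weights. Result lies in [0, 1].
    """
    S = np.asarray(scores, dtype=np.float64)
    C = np.asarray(covariates, dtype=np.float64)
    if C.ndim == 1:
        C = C[:, None]
    design = np.hstack([np.ones((S.shape[0], 1)), C])
    beta, *_ = np.linalg.lstsq(design, S, rcond=None)
    resid = S - design @ beta
    ss_res = (resid**2).sum(axis=0)
    ss_tot = ((S - S.mean(axis=0, keepdims=True)) ** 2).sum(axis=0)
    r2 = np.where(ss_tot > 0, 1.0 - ss_res / np.maximum(ss_tot, 1e-300), 0.0)
    r2 = np.clip(r2, 0.0, 1.0)
    w = np.asarray(variances, dtype=np.float64)
    return float((w * r2).sum() / w.sum())
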