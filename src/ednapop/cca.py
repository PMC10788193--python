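"""Canonical correspondence analysis (CCA) with a permutation ANOVA.

Constrained ordination of a samples x taxa count matrix against
explanatory variables (here a depth gradient): the table is converted to
chi-square standardized residuals, projected onto the row-weighted
constraint space, and the fitted and residual parts are decomposed
spectrally.  Total inertia (the table's chi-square statistic over its
grand total) splits exactly into constrained + unconstrained parts.  The
association with the constraints is tested by a pseudo-F statistic whose
null distribution comes from permuting the rows of the constraint
matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CcaResult", "cca", "permutation_anova"]


@dataclass
class CcaResult:
    constrained_eigenvalues: np.ndarray
    unconstrained_eigenvalues: np.ndarray
    site_scores: np.ndarray          # samples x constrained axes (LC scores)
    site_scores_wa: np.ndarray       # weighted-average (species-derived) scores
    total_inertia: float
    constrained_inertia: float
    residual_inertia: float
    pseudo_F: float
    df: tuple                        # (q, n - q - 1)
    permutation_p: float | None = None
    n_permutations: int = 0


def _chi_square_residuals(Y: np.ndarray):
    """Relative-frequency table -> standardized residual matrix Qbar,
    with row and column weight vectors."""
    total = Y.sum()
    if total <= 0:
        raise ValueError("community table has no counts")
    P = Y / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    if np.any(r <= 0):
        raise ValueError("sample with zero total count: remove it first")
    expected = np.outer(r, c)
    Qbar = (P - expected) / np.sqrt(expected)
    return Qbar, r, c


def _prepare(community, constraints):
    Y = np.asarray(
        community.values if isinstance(community, pd.DataFrame) else community,
        dtype=float,
    )
    if np.any(Y < 0):
        raise ValueError("negative counts in community matrix")
    X = np.asarray(
        constraints.values if isinstance(constraints, pd.DataFrame) else constraints,
        dtype=float,
    )
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("constraints and community must have matching samples")
    keep = Y.sum(axis=0) > 0
    Y = Y[:, keep]  # taxa never observed carry no inertia
    return Y, X


def _constrained_fit(Qbar, r, X):
    """Project the residual matrix onto the row-weighted constraint
    space; returns (fitted matrix, weighted design Xw)."""
    w = np.sqrt(r)
    Xc = X - (r @ X)[None, :]          # weighted column centering
    Xw = w[:, None] * Xc
    q = X.shape[1]
    if np.linalg.matrix_rank(Xw) < q:
        raise ValueError("constraint matrix is rank deficient after weighted centering")
    coef, *_ = np.linalg.lstsq(Xw, Qbar, rcond=None)
    return Xw @ coef, Xw


def cca(community, constraints) -> CcaResult:
    """Canonical correspondence analysis of counts on constraints.

    ``community``: samples x taxa non-negative counts (DataFrame or
    array); ``constraints``: samples x q numeric matrix (q < n - 1,
    full rank).  Returns eigenvalues of the constrained and residual
    parts, linear-combination and weighted-average site scores on the
    constrained axes, the inertia decomposition and the pseudo-F
    statistic with its (q, n - q - 1) degrees of freedom.
    """
    Y, X = _prepare(community, constraints)
    n, q = X.shape[0], X.shape[1]
    if n < 2:
        raise ValueError("need >= 2 samples")
    if q >= n - 1:
        raise ValueError("need q < n - 1 constraints")
    Qbar, r, c = _chi_square_residuals(Y)
    total_inertia = float((Qbar ** 2).sum())
    fitted, _ = _constrained_fit(Qbar, r, X)
    U, S, Vt = np.linalg.svd(fitted, full_matrices=False)
    n_axes = min(q, len(S))
    eig_c = (S ** 2)[:n_axes]
    resid = Qbar - fitted
    S_r = np.linalg.svd(resid, compute_uv=False)
    eig_u = S_r[S_r ** 2 > 1e-12] ** 2
    constrained_inertia = float(eig_c.sum())
    residual_inertia = max(total_inertia - constrained_inertia, 0.0)
    dfr = n - q - 1
    if residual_inertia <= 1e-12 * max(total_inertia, 1.0):
        pseudo_F = np.inf  # constraints absorb the whole inertia
    else:
        pseudo_F = (constrained_inertia / q) / (residual_inertia / dfr)
    inv_w = 1.0 / np.sqrt(r)
    lc = inv_w[:, None] * (U[:, :n_axes] * S[:n_axes][None, :])
    wa = inv_w[:, None] * (Qbar @ Vt[:n_axes].T)
    return CcaResult(
        constrained_eigenvalues=eig_c,
        unconstrained_eigenvalues=eig_u,
        site_scores=lc,
        site_scores_wa=wa,
        total_inertia=total_inertia,
        constrained_inertia=constrained_inertia,
        residual_inertia=residual_inertia,
        pseudo_F=float(pseudo_F),
        df=(q, dfr),
    )


def permutation_anova(
    community,
    constraints,
    n_perm: int = 10000,
    seed: int = 0,
) -> CcaResult:
    """Permutation test of the CCA constraints.

    The observed pseudo-F is compared with its distribution under random
    permutation of the constraint-matrix rows (the community table and
    its row weights stay fixed); p uses the add-one Monte-Carlo
    estimator (1 + #{F_perm >= F_obs}) / (1 + n_perm), which never
    returns zero.
    """
    if n_perm < 99:
        warnings.warn(f"n_perm={n_perm} gives poor p-value resolution; use >= 99")
    result = cca(community, constraints)
    Y, X = _prepare(community, constraints)
    n, q = X.shape
    Qbar, r, _ = _chi_square_residuals(Y)
    total = result.total_inertia
    dfr = n - q - 1
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        Xp = X[rng.permutation(n)]
        fitted, _ = _constrained_fit(Qbar, r, Xp)
        ci = float((fitted ** 2).sum())
        resid = max(total - ci, 0.0)
        if resid <= 1e-12 * max(total, 1.0):
            F = np.inf
        else:
            F = (ci / q) / (resid / dfr)
        if F >= result.pseudo_F - 1e-12:
            exceed += 1
    result.permutation_p = (1 + exceed) / (1 + n_perm)
    result.n_permutations = n_perm
    return result
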