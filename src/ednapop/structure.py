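"""Population-structure inference.

Covers the tissue-genotype side of the analysis: composite-genotype
linkage disequilibrium and windowed LD pruning, a K-component admixture
model fit by EM on biallelic dosages, a pooled-sample (pool-seq-style)
ancestry estimator for eDNA read counts, and a NIPALS PCA that tolerates
missing cells in allele-frequency matrices.

The admixture model treats each individual's two allele draws at a locus
as a mixture over K ancestral components with component allele
frequencies P and individual ancestry proportions Q; the EM iterations
are the classical responsibility-weighted averages and the likelihood is
non-decreasing by construction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "AncestryEstimate",
    "PoolAncestry",
    "PcaResult",
    "ld_r2",
    "ld_prune",
    "admixture_em",
    "estimate_pool_ancestry",
    "pca_missing",
]

_EPS = 1e-6


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs reference-allele dosages (0/1/2, NaN missing)."""

    dosages: np.ndarray          # (n_ind, n_snps) float with NaN for missing
    individual_ids: list
    snp_ids: list
    strata: list                 # per-individual depth-stratum label
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None  # 1-based

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if len(self.individual_ids) != n or len(self.strata) != n:
            raise ValueError("individual metadata length mismatch")
        if len(self.snp_ids) != m:
            raise ValueError("snp_ids length mismatch")
        obs = self.dosages[~np.isnan(self.dosages)]
        if obs.size and (np.any(obs < 0) | np.any(obs > 2) | np.any(obs != np.round(obs))):
            raise ValueError("dosages must be integral in {0, 1, 2} or NaN")
        if self.pos is not None:
            self.pos = np.asarray(self.pos, dtype=np.int64)
            self.chrom = np.asarray(self.chrom)
            for c in np.unique(self.chrom):
                p = self.pos[self.chrom == c]
                if np.any(np.diff(p) < 0):
                    raise ValueError(
                        f"positions unsorted within chromosome {c}; sort the input"
                    )

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        idx = [self.snp_ids.index(s) for s in snp_ids]
        return GenotypeMatrix(
            self.dosages[:, idx], list(self.individual_ids), list(snp_ids),
            list(self.strata),
            None if self.chrom is None else self.chrom[idx],
            None if self.pos is None else self.pos[idx],
        )


@dataclass
class AncestryEstimate:
    """Admixture fit: Q (individuals x K), P (K x SNPs), and the EM trace."""

    Q: np.ndarray
    P: np.ndarray
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int

    def __post_init__(self):
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("Q rows must sum to 1")


@dataclass
class PoolAncestry:
    """Pooled-sample ancestry estimate with profile-likelihood interval."""

    q_hat: float
    interval: tuple
    loglik: float
    flat: bool = False


@dataclass
class PcaResult:
    scores: np.ndarray            # samples x components
    loadings: np.ndarray          # SNPs x components
    explained_variance: np.ndarray
    method: str = "nipals"
    dropped_columns: list = field(default_factory=list)


# ----------------------------------------------------------------- LD


def ld_r2(dosage_i, dosage_j) -> float:
    """Composite-genotype LD: squared Pearson correlation of two dosage
    vectors over pairwise-complete individuals.

    Monomorphic vectors make r^2 undefined; for pruning purposes this is
    treated as 0 with a warning.
    """
    x = np.asarray(dosage_i, dtype=float)
    y = np.asarray(dosage_j, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3:
        raise ValueError("need >= 3 pairwise-complete individuals")
    x, y = x[ok], y[ok]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        warnings.warn("monomorphic dosage vector: r^2 undefined, treated as 0")
        return 0.0
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r


def ld_prune(
    genotypes: GenotypeMatrix,
    window_kb: float = 50.0,
    step: int = 10,
    r2_threshold: float = 0.1,
    step_unit: str = "variants",
) -> list:
    """Greedy windowed LD pruning; returns kept SNP ids in input order.

    Within each window of ``window_kb`` kb, any pair with r^2 above the
    threshold loses its later member (by position).  Windows advance by
    ``step`` variants (or base pairs with ``step_unit='bp'``);
    chromosomes are pruned independently.  A final per-variant sweep
    guarantees that no retained pair within a window exceeds the
    threshold, so the output is a fixed point of re-pruning.
    """
    if genotypes.pos is None:
        raise ValueError("ld_prune requires chrom/pos annotations")
    if step_unit not in ("variants", "bp"):
        raise ValueError("step_unit must be 'variants' or 'bp'")
    span = window_kb * 1000.0
    kept_mask = np.ones(genotypes.n_snps, dtype=bool)
    D = genotypes.dosages

    def prune_window(idx):
        # idx: global indices inside one window, position-sorted
        for a_i, a in enumerate(idx):
            if not kept_mask[a]:
                continue
            for b in idx[a_i + 1:]:
                if not kept_mask[b]:
                    continue
                if ld_r2(D[:, a], D[:, b]) > r2_threshold:
                    kept_mask[b] = False  # drop the later SNP

    for c in np.unique(genotypes.chrom):
        cidx = np.flatnonzero(genotypes.chrom == c)
        pos = genotypes.pos[cidx]
        n = len(cidx)
        starts = range(0, n, step) if step_unit == "variants" else None
        if step_unit == "bp":
            starts, last = [], -np.inf
            for i in range(n):
                if pos[i] >= last + step:
                    starts.append(i)
                    last = pos[i]
        for i0 in starts:
            in_win = cidx[(pos >= pos[i0]) & (pos < pos[i0] + span)]
            prune_window(list(in_win))
        # validity sweep: every kept variant heads a window once
        for i0 in range(n):
            if not kept_mask[cidx[i0]]:
                continue
            in_win = cidx[(pos >= pos[i0]) & (pos < pos[i0] + span)]
            prune_window([g for g in in_win if kept_mask[g]])

    return [s for s, k in zip(genotypes.snp_ids, kept_mask) if k]


# ----------------------------------------------------------- admixture


def admixture_em(
    genotypes: GenotypeMatrix,
    K: int = 2,
    max_iter: int = 2000,
    tol: float = 1e-6,
    seed: int = 0,
) -> AncestryEstimate:
    """Fit the K-component admixture model to dosages by EM.

    Maximizes sum_il [g_il log f_il + (2 - g_il) log(1 - f_il)] with
    f_il = sum_k q_ik p_kl over Q (rows on the simplex) and P (clamped to
    [1e-6, 1 - 1e-6]).  Missing genotypes contribute nothing.  Q is
    initialized from a symmetric Dirichlet draw, P from the overall
    allele frequency perturbed by +/- 0.05 per component.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    G = genotypes.dosages
    n, L = G.shape
    mask = ~np.isnan(G)
    if not mask.any():
        raise ValueError("all genotypes missing")
    Gz = np.where(mask, G, 0.0)       # zero-filled for arithmetic
    G2z = np.where(mask, 2.0 - G, 0.0)
    n_obs = mask.sum(axis=1)          # loci observed per individual
    if np.any(n_obs == 0):
        raise ValueError("individual with no observed genotypes")

    rng = np.random.default_rng(seed)
    Q = rng.dirichlet(np.ones(K), size=n)
    base = Gz.sum(axis=0) / np.maximum(2.0 * mask.sum(axis=0), 1.0)
    P = np.clip(
        base[None, :] + rng.uniform(-0.05, 0.05, size=(K, L)), _EPS, 1 - _EPS
    )

    def loglik(Q, P):
        F = np.clip(Q @ P, _EPS, 1 - _EPS)
        return float(np.sum(Gz * np.log(F) + G2z * np.log1p(-F)))

    trace = [loglik(Q, P)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        F = np.clip(Q @ P, _EPS, 1 - _EPS)
        # responsibilities: expected allele draws per component
        A = np.zeros((K, n, L))       # reference-allele draws
        B = np.zeros((K, n, L))       # alternate-allele draws
        for k in range(K):
            A[k] = Gz * (Q[:, k:k + 1] * P[k][None, :]) / F
            B[k] = G2z * (Q[:, k:k + 1] * (1.0 - P[k])[None, :]) / (1.0 - F)
        AB = A + B
        Q = AB.sum(axis=2).T / (2.0 * n_obs)[:, None]
        Q /= Q.sum(axis=1, keepdims=True)
        denom = AB.sum(axis=1)
        P = np.clip(A.sum(axis=1) / np.maximum(denom, 1e-300), _EPS, 1 - _EPS)
        trace.append(loglik(Q, P))
        if trace[-1] - trace[-2] < tol:
            converged = True
            break
    if not converged:
        logger.warning("admixture EM hit max_iter=%d without converging", max_iter)
    return AncestryEstimate(Q, P, np.asarray(trace), converged, it)


def align_components(Q_hat: np.ndarray, q_true: np.ndarray) -> np.ndarray:
    """Resolve two-component label switching against a truth vector:
    returns the column of Q_hat (possibly swapped) matching q_true with
    the smaller mean absolute error."""
    if Q_hat.shape[1] != 2:
        raise ValueError("alignment helper supports K=2 only")
    e0 = np.mean(np.abs(Q_hat[:, 0] - q_true))
    e1 = np.mean(np.abs(Q_hat[:, 1] - q_true))
    return Q_hat[:, 0] if e0 <= e1 else Q_hat[:, 1]


# -------------------------------------------------- pooled eDNA ancestry


def estimate_pool_ancestry(
    ref_counts,
    total_counts,
    p1,
    p2,
    grid: int = 1001,
) -> PoolAncestry:
    """Estimate the shallow-ancestry fraction q of a pooled eDNA sample.

    Under the pooled model the reference-allele frequency at locus l is
    f_l = q p1_l + (1 - q) p2_l; read counts are binomial draws, so the
    log-likelihood is sum_l [x_l log f_l + (n_l - x_l) log(1 - f_l)].
    Maximized on a dense grid over [0, 1] with local refinement; the
    reported interval is the profile-likelihood region where the
    log-likelihood is within 1.92 of its maximum (asymptotic 95%).

    When p1 == p2 everywhere the likelihood is flat in q: the estimate is
    undefined and ``flat`` is set.
    """
    x = np.asarray(ref_counts, dtype=float)
    ntot = np.asarray(total_counts, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    use = ntot > 0
    x, ntot, p1, p2 = x[use], ntot[use], p1[use], p2[use]
    if np.max(np.abs(p1 - p2), initial=0.0) < 1e-12:
        warnings.warn("p1 == p2 at every locus: pooled-ancestry likelihood is flat")
        return PoolAncestry(np.nan, (0.0, 1.0), np.nan, flat=True)

    def negll(q):
        f = np.clip(q * p1 + (1 - q) * p2, _EPS, 1 - _EPS)
        return -float(np.sum(x * np.log(f) + (ntot - x) * np.log1p(-f)))

    qs = np.linspace(0.0, 1.0, grid)
    lls = -np.array([negll(q) for q in qs])
    best = int(np.argmax(lls))
    lo_b = qs[max(best - 1, 0)]
    hi_b = qs[min(best + 1, grid - 1)]
    res = minimize_scalar(negll, bounds=(lo_b, hi_b), method="bounded")
    q_hat = float(res.x)
    ll_max = max(-res.fun, lls[best])
    inside = qs[lls >= ll_max - 1.92]
    interval = (float(inside.min()), float(inside.max()))
    return PoolAncestry(q_hat, interval, ll_max)


# --------------------------------------------------------------- PCA


def pca_missing(
    X,
    n_components: int = 2,
    method: str = "nipals",
    max_iter: int = 2000,
    tol: float = 1e-12,
) -> PcaResult:
    """PCA of a samples x SNPs matrix tolerating missing (NaN) cells.

    Columns are mean-centered over their observed entries, then
    components are extracted one at a time by NIPALS iteration that skips
    missing cells.  On complete data the result coincides with the
    truncated singular-value decomposition (up to sign); signs are fixed
    so the largest-magnitude loading of each component is positive.
    All-missing columns are dropped with a warning.
    """
    if method != "nipals":
        raise ValueError("only NIPALS is implemented")
    X = np.asarray(X, dtype=float).copy()
    n, m = X.shape
    if n < 2:
        raise ValueError("need >= 2 samples")
    obs = ~np.isnan(X)
    all_missing = np.flatnonzero(~obs.any(axis=0))
    if all_missing.size:
        warnings.warn(f"dropping {all_missing.size} all-missing column(s)")
    keep = np.flatnonzero(obs.any(axis=0))
    X = X[:, keep]
    obs = obs[:, keep]
    m = X.shape[1]
    n_components = min(n_components, n - 1, m)

    col_mean = np.nanmean(X, axis=0)
    R = np.where(obs, X - col_mean[None, :], 0.0)  # residual, zeros at missing

    scores = np.zeros((n, n_components))
    loadings = np.zeros((m, n_components))
    expvar = np.zeros(n_components)
    for comp in range(n_components):
        # start from the column with the largest observed variance
        t = R[:, int(np.argmax((R ** 2).sum(axis=0)))].copy()
        if not np.any(t):
            break
        for _ in range(max_iter):
            # loadings regression, cell-wise over observed entries
            tw = np.where(obs, t[:, None], 0.0)
            p = (R * tw).sum(axis=0) / np.maximum((tw ** 2).sum(axis=0), 1e-300)
            p /= np.linalg.norm(p)
            pw = np.where(obs, p[None, :], 0.0)
            t_new = (R * pw).sum(axis=1) / np.maximum((pw ** 2).sum(axis=1), 1e-300)
            if np.linalg.norm(t_new - t) <= tol * max(np.linalg.norm(t_new), 1e-300):
                t = t_new
                break
            t = t_new
        if np.max(np.abs(p)) > 0 and p[int(np.argmax(np.abs(p)))] < 0:
            p, t = -p, -t
        scores[:, comp] = t
        loadings[:, comp] = p
        expvar[comp] = float(t @ t) / (n - 1)
        R = np.where(obs, R - np.outer(t, p), 0.0)

    return PcaResult(scores, loadings, expvar, "nipals", list(all_missing))
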