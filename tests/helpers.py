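"""Shared test fixtures and independent reference implementations."""

import numpy as np

from ednapop import GenotypeMatrix


def geno(dosages, chrom=None, pos=None, strata=None):
    d = np.asarray(dosages, dtype=float)
    n, m = d.shape
    return GenotypeMatrix(
        d, [f"i{k}" for k in range(n)], [f"v{j}" for j in range(m)],
        strata or ["0-5"] * n,
        None if chrom is None else np.asarray(chrom),
        None if pos is None else np.asarray(pos),
    )


def correlated_fixture(n_snps=200, n_ind=60, seed=5):
    """SNPs in linked blocks: every third SNP is a jittered copy of its
    predecessor; positions spread over ~100 kb of one chromosome."""
    rng = np.random.default_rng(seed)
    d = rng.binomial(2, rng.uniform(0.2, 0.8, n_snps), size=(n_ind, n_snps)).astype(float)
    for j in range(1, n_snps, 3):
        flip = rng.random(n_ind) < 0.05
        d[:, j] = np.where(flip, rng.binomial(2, 0.5, n_ind), d[:, j - 1])
    pos = np.sort(rng.choice(np.arange(1, 100_000), size=n_snps, replace=False))
    return geno(d, chrom=["chr1"] * n_snps, pos=pos)


def two_step_reference(Y, X):
    """Independent textbook CCA: explicit cell loops for the chi-square
    residuals, normal-equation weighted regression, and eigenvalues from
    cross-product matrices."""
    Y = np.asarray(Y, float)
    X = np.asarray(X, float)
    n, m = Y.shape
    total = Y.sum()
    P = Y / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    Q = np.empty_like(P)
    for i in range(n):
        for j in range(m):
            e = r[i] * c[j]
            Q[i, j] = (P[i, j] - e) / np.sqrt(e)
    xbar = np.array([np.sum(r * X[:, k]) for k in range(X.shape[1])])
    Xc = X - xbar[None, :]
    Xw = np.sqrt(r)[:, None] * Xc
    B = np.linalg.solve(Xw.T @ Xw, Xw.T @ Q)
    fitted = Xw @ B
    eig = np.linalg.eigvalsh(fitted.T @ fitted)[::-1]
    eig_resid = np.linalg.eigvalsh((Q - fitted).T @ (Q - fitted))[::-1]
    return eig[eig > 1e-12], eig_resid[eig_resid > 1e-12], float((Q ** 2).sum())
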