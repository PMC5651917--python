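"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives a quantity by the most literal route available —
per-meiosis selfing for RIL genotypes, per-locus outer-product loops for
kinship, dense likelihood evaluation on a grid for REML — deliberately
avoiding the shortcuts (fixation-level Markov walk, matrix products,
eigendecomposition profiling) used by the package.
"""

from __future__ import annotations

import numpy as np


def selfing_ril_simulator(positions_cm: np.ndarray, n: int, seed: int,
                          generations: int = 60) -> np.ndarray:
    """Generation-explicit RIL simulator for one chromosome.

    Starts from F1 individuals heterozygous at every locus (haplotype A
    from parent 1, haplotype B from parent 2) and selfs each line for up to
    ``generations`` meioses.  Every gamete is built by a literal meiosis:
    parental origin at the first locus is a fair coin, and origin switches
    between adjacent loci with the Haldane single-meiosis recombination
    fraction r = (1 - exp(-2d/100))/2.  Returns codes in {-1, +1} (residual
    heterozygosity after 60 selfing generations is ~1e-18 per locus and is
    resolved by the first haplotype).
    """
    rng = np.random.default_rng(seed)
    pos = np.asarray(positions_cm, dtype=float)
    m = pos.size
    r = 0.5 * (1.0 - np.exp(-2.0 * np.diff(pos) / 100.0))
    hapA = np.zeros((n, m), dtype=np.int8)   # parent-1 origin everywhere
    hapB = np.ones((n, m), dtype=np.int8)

    def gamete(hA, hB):
        origin = np.empty((n, m), dtype=np.int8)
        origin[:, 0] = rng.integers(0, 2, size=n)
        if m > 1:
            switch = rng.random((n, m - 1)) < r[None, :]
            origin[:, 1:] = switch
            origin = np.cumsum(origin, axis=1) % 2
        return np.where(origin == 0, hA, hB)

    for _ in range(generations):
        if np.array_equal(hapA, hapB):
            break
        g1 = gamete(hapA, hapB)
        g2 = gamete(hapA, hapB)
        hapA, hapB = g1, g2
    return np.where(hapA == 0, 1, -1).astype(np.int8)


def kinship_loop(Z: np.ndarray) -> np.ndarray:
    """K' by the defining per-locus outer-product sum, one locus at a time."""
    n, m = Z.shape
    K = np.zeros((n, n))
    for k in range(m):
        zk = Z[:, k].astype(float)
        K += np.outer(zk, zk)
    return K / m


def dense_loglik(y, X, K, sigma_A2, sigma2, method="REML"):
    """Literal dense evaluation of the (restricted) log-likelihood.

    Builds V = K sigma_A2 + I sigma2 explicitly, takes log-determinants and
    solves directly — no eigendecomposition, no profiling.
    """
    n = y.size
    V = sigma_A2 * K + sigma2 * np.eye(n)
    sign, logdetV = np.linalg.slogdet(V)
    if sign <= 0:
        return -np.inf
    Vi_X = np.linalg.solve(V, X)
    Vi_y = np.linalg.solve(V, y)
    XtViX = X.T @ Vi_X
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    resid = y - X @ beta
    quad = float(resid @ (Vi_y - Vi_X @ beta))
    L = -0.5 * (logdetV + quad)
    if method == "REML":
        s2, logdetX = np.linalg.slogdet(XtViX)
        if s2 <= 0:
            return -np.inf
        L -= 0.5 * logdetX
    return L


def dense_loglik_grid(y, X, K, sA2_grid, s2_grid, method="REML",
                      chunk: int = 2000) -> np.ndarray:
    """Dense log-likelihood surface over a (sigma_A2, sigma2) grid.

    Same literal route as :func:`dense_loglik`, batched over grid points in
    chunks with stacked linear algebra.  Returns an array of shape
    (len(sA2_grid), len(s2_grid)).
    """
    n, q = X.shape
    A, S = np.meshgrid(np.asarray(sA2_grid), np.asarray(s2_grid),
                       indexing="ij")
    a, s = A.ravel(), S.ravel()
    out = np.empty(a.size)
    I = np.eye(n)
    for start in range(0, a.size, chunk):
        sl = slice(start, min(start + chunk, a.size))
        V = a[sl, None, None] * K[None] + s[sl, None, None] * I[None]
        sign, logdetV = np.linalg.slogdet(V)
        Vi_X = np.linalg.solve(V, np.broadcast_to(X, (V.shape[0], n, q)))
        Vi_y = np.linalg.solve(V, np.broadcast_to(y[:, None], (V.shape[0], n, 1)))[..., 0]
        XtViX = np.einsum("nk,gnq->gkq", X, Vi_X)
        beta = np.linalg.solve(
            XtViX, np.einsum("nk,gn->gk", X, Vi_y)[..., None])[..., 0]
        resid = y[None, :] - np.einsum("nq,gq->gn", X, beta)
        Vi_resid = Vi_y - np.einsum("gnq,gq->gn", Vi_X, beta)
        quad = np.einsum("gn,gn->g", resid, Vi_resid)
        L = -0.5 * (logdetV + quad)
        if method == "REML":
            s2sign, logdetX = np.linalg.slogdet(XtViX)
            L = L - 0.5 * logdetX
            L = np.where((sign <= 0) | (s2sign <= 0), -np.inf, L)
        else:
            L = np.where(sign <= 0, -np.inf, L)
        out[sl] = L
    return out.reshape(A.shape)


def two_pass_variance(x: np.ndarray) -> float:
    """Hand-rolled two-pass sample variance with the n-1 denominator."""
    x = np.asarray(x, dtype=float)
    mean = x.sum() / x.size
    return float(((x - mean) ** 2).sum() / (x.size - 1))
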