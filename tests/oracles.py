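"""Independent reference implementations used to pin down the package's
estimators.  Everything here is written directly from the textbook
definitions (sums over sites and samples, normal equations, IRLS,
combinatorial enumeration) and deliberately shares no code with the package.
"""

from __future__ import annotations

import math

import numpy as np


def tajimas_d_from_counts(minor_counts: list[int], n: int) -> float:
    """Tajima's D from folded minor allele counts at S segregating sites.

    theta_pi is the mean number of pairwise differences,
    sum_s i_s (n - i_s) / C(n, 2); theta_w = S / a1; the variance uses the
    1989 constants written out term by term.
    """
    s = len(minor_counts)
    if s == 0:
        return float("nan")
    pairs = n * (n - 1) / 2.0
    theta_pi = sum(i * (n - i) for i in minor_counts) / pairs
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    theta_w = s / a1
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    var = e1 * s + e2 * s * (s - 1)
    return (theta_pi - theta_w) / math.sqrt(var)


def theta_pi_from_counts(minor_counts: list[int], n: int) -> float:
    """Mean pairwise differences: sum_s i(n - i) / C(n, 2)."""
    pairs = n * (n - 1) / 2.0
    return sum(i * (n - i) for i in minor_counts) / pairs


def ols_normal_equations(x: np.ndarray, y: np.ndarray):
    """OLS via the normal equations: beta, se, t, r2."""
    xtx = x.T @ x
    beta = np.linalg.solve(xtx, x.T @ y)
    resid = y - x @ beta
    n, k = x.shape
    sigma2 = resid @ resid / (n - k)
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(xtx)))
    tss = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - (resid @ resid) / tss
    return beta, se, beta / se, r2


def poisson_irls(x: np.ndarray, y: np.ndarray, tol=1e-12, max_iter=200):
    """Poisson log-link GLM by hand-rolled IRLS; returns (beta, deviance)."""
    beta = np.zeros(x.shape[1])
    beta[0] = np.log(max(y.mean(), 1e-8))
    for _ in range(max_iter):
        eta = x @ beta
        mu = np.exp(eta)
        w = mu
        z = eta + (y - mu) / mu
        xtwx = x.T @ (w[:, None] * x)
        new = np.linalg.solve(xtwx, x.T @ (w * z))
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    mu = np.exp(x @ beta)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    deviance = 2.0 * np.sum(term - (y - mu))
    return beta, deviance


def hypergeom_upper_tail(n_univ: int, big_k: int, n_draw: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n) by exact enumeration."""
    total = math.comb(n_univ, n_draw)
    acc = 0
    for j in range(k, min(big_k, n_draw) + 1):
        acc += math.comb(big_k, j) * math.comb(n_univ - big_k, n_draw - j)
    return acc / total


def compound_binomial_read_var(p: float, n_pool: int, depths: np.ndarray) -> float:
    """Variance of the read frequency under two-stage pool sampling.

    Conditional on depth d: Var = pq/n + pq(1 - 1/n)/d; averaged over the
    realised depths.
    """
    pq = p * (1.0 - p)
    inv_d = np.mean(1.0 / depths)
    return pq / n_pool + pq * (1.0 - 1.0 / n_pool) * inv_d
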