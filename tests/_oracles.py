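"""Independent oracles used to cross-check the implementation.

These deliberately avoid the package's own code paths: plain logistic
regression comes from statsmodels' IRLS, the mixed-model marginal likelihood
from adaptive Gauss-Hermite quadrature, and small regressions from numpy
closed forms.
"""

from __future__ import annotations

import itertools

import numpy as np
import statsmodels.api as sm
from scipy.special import expit, logsumexp


def irls_logistic(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Plain logistic MLE via statsmodels GLM (IRLS). Returns (beta, loglik)."""
    model = sm.GLM(y, X, family=sm.families.Binomial())
    res = model.fit(tol=1e-12, maxiter=200)
    return np.asarray(res.params), float(res.llf)


def agq_loglik(
    beta: np.ndarray,
    sigma: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    yi: np.ndarray,
    y: np.ndarray,
    n_nodes: int = 15,
) -> float:
    """Marginal Bernoulli-mixed log-likelihood by adaptive Gauss-Hermite quadrature.

    Random effects are ``b_j = sigma * u_j`` with standard-normal ``u_j``;
    the per-year integral is evaluated on a mode/curvature-adapted tensor
    grid of ``n_nodes`` Hermite nodes per dimension.
    """
    offset = X @ beta
    Zs = Z * sigma
    q = Z.shape[1]
    J = int(yi.max()) + 1

    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    grid = np.array(list(itertools.product(range(n_nodes), repeat=q)))
    zpts = nodes[grid]  # (K, q)
    log_w = np.log(weights)[grid].sum(axis=1) + (zpts**2).sum(axis=1)

    total = 0.0
    for j in range(J):
        rows = yi == j
        off_j, Zs_j, y_j = offset[rows], Zs[rows], y[rows]

        u = np.zeros(q)
        for _ in range(200):
            eta = off_j + Zs_j @ u
            p = expit(eta)
            g = Zs_j.T @ (y_j - p) - u
            H = Zs_j.T @ (Zs_j * (p * (1 - p))[:, None]) + np.eye(q)
            if np.max(np.abs(g)) < 1e-12:
                break
            u = u + np.linalg.solve(H, g)

        L = np.linalg.cholesky(H)
        A = np.linalg.inv(L).T  # A A' = H^{-1}
        U = u + np.sqrt(2.0) * zpts @ A.T  # (K, q)
        eta = off_j[None, :] + U @ Zs_j.T  # (K, n_j)
        h = (y_j * eta - np.logaddexp(0.0, eta)).sum(axis=1)
        h += -0.5 * (U**2).sum(axis=1) - 0.5 * q * np.log(2.0 * np.pi)
        log_det_a = -np.log(np.diag(L)).sum()
        total += logsumexp(log_w + h) + 0.5 * q * np.log(2.0) + log_det_a
    return float(total)


def ols_line(x, y) -> tuple[float, float]:
    """Closed-form simple regression: returns (slope, intercept)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    slope = np.cov(x, y, ddof=0)[0, 1] / np.var(x)
    return float(slope), float(y.mean() - slope * x.mean())
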