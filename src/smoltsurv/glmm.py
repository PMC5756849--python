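"""Bernoulli/logit mixed model with independent year-level random effects.

The marginal likelihood integrates the per-year random effects out of the
Bernoulli likelihood; each per-year integral is replaced by its Laplace
approximation around the conditional mode.  Random effects are parametrized
as ``b_j = sigma * u_j`` with standard-normal ``u_j``, which keeps the
objective smooth down to the ``sigma = 0`` boundary.  Optimization is
quasi-Newton (L-BFGS-B) over fixed effects and the sigma vector, with an
inner damped-Newton solve for the conditional modes of every year.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from smoltsurv.covariates import CovariateTable
from smoltsurv.model_space import ModelSpace, ModelSpec

__all__ = ["ModelFit", "aicc", "fit_glmm", "fit_model_space", "predict_survival"]

logger = logging.getLogger(__name__)

#: Estimated standard deviations below this are reported as exactly 0.
SIGMA_FLOOR = 1e-6

#: Fixed-effect magnitude beyond which a fit is flagged as likely separated.
SEPARATION_BETA = 15.0

RANDOM_COLUMNS = ("b0", "b1", "b2")


@dataclass
class ModelFit:
    """A fitted candidate model.

    ``beta_names`` lists the fixed-effect columns (``intercept`` first);
    ``sigma_hat`` holds the standard deviations of the active random terms
    (intercept[, slope on d[, slope on d2]]); ``cov_beta`` is the estimated
    covariance of ``beta_hat``; ``conditional_modes`` the per-year empirical
    Bayes modes on the ``b`` scale.
    """

    spec: ModelSpec
    beta_names: tuple[str, ...]
    beta_hat: np.ndarray
    sigma_hat: np.ndarray
    cov_beta: np.ndarray
    loglik: float
    k: int
    n: int
    aicc: float
    converged: bool
    separation: bool
    conditional_modes: pd.DataFrame

    @property
    def beta(self) -> dict[str, float]:
        return dict(zip(self.beta_names, self.beta_hat))

    def se_beta(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov_beta), 0.0, None))

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "beta_names": list(self.beta_names),
            "beta_hat": self.beta_hat.tolist(),
            "sigma_hat": self.sigma_hat.tolist(),
            "cov_beta": self.cov_beta.tolist(),
            "loglik": self.loglik,
            "k": self.k,
            "n": self.n,
            "aicc": self.aicc,
            "converged": self.converged,
            "separation": self.separation,
            "conditional_modes": {
                "years": [int(y) for y in self.conditional_modes.index],
                "columns": list(self.conditional_modes.columns),
                "values": self.conditional_modes.to_numpy().tolist(),
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelFit":
        cm = d["conditional_modes"]
        return cls(
            spec=ModelSpec.from_dict(d["spec"]),
            beta_names=tuple(d["beta_names"]),
            beta_hat=np.asarray(d["beta_hat"], dtype=float),
            sigma_hat=np.asarray(d["sigma_hat"], dtype=float),
            cov_beta=np.asarray(d["cov_beta"], dtype=float),
            loglik=d["loglik"],
            k=d["k"],
            n=d["n"],
            aicc=d["aicc"],
            converged=d["converged"],
            separation=d["separation"],
            conditional_modes=pd.DataFrame(
                cm["values"], index=pd.Index(cm["years"], name="year"), columns=cm["columns"]
            ),
        )

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path) -> "ModelFit":
        return cls.from_dict(json.loads(Path(path).read_text()))


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: ``-2*loglik + 2k + 2k(k+1)/(n-k-1)``."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _bernoulli_loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # y*eta - log(1 + exp(eta)), computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def _design_matrices(table: CovariateTable, spec: ModelSpec):
    df = table.data
    names = ("intercept",) + spec.fixed_names
    cols = [np.ones(len(df))] + [df[c].to_numpy(float) for c in spec.fixed_names]
    X = np.column_stack(cols)
    q = spec.n_random
    zcols = [np.ones(len(df)), df["d"].to_numpy(float), df["d2"].to_numpy(float)][:q]
    Z = np.column_stack(zcols)
    years, yi = np.unique(df["year"].to_numpy(), return_inverse=True)
    y = df["y"].to_numpy(float)
    return X, names, Z, years, yi, y


def _newton_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-10):
    """Plain logistic MLE via damped Newton; also the warm start for mixed fits."""
    p_dim = X.shape[1]
    beta = np.zeros(p_dim)
    ll = _bernoulli_loglik(X @ beta, y)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        grad = X.T @ (y - mu)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        w = mu * (1.0 - mu)
        H = X.T @ (X * w[:, None]) + 1e-12 * np.eye(p_dim)
        step = np.linalg.solve(H, grad)
        # step-halving keeps the likelihood monotone under separation drift
        for _ in range(30):
            cand = beta + step
            ll_new = _bernoulli_loglik(X @ cand, y)
            if ll_new >= ll - 1e-12:
                break
            step *= 0.5
        beta = beta + step
        ll = ll_new
    return beta, ll, converged


class _LaplaceObjective:
    """Negative Laplace log-likelihood with a warm-started inner mode solve."""

    def __init__(self, X, Z, yi, y, n_years):
        self.X, self.Z, self.yi, self.y = X, Z, yi, y
        self.J = n_years
        self.q = Z.shape[1]
        self.p = X.shape[1]
        self.u = np.zeros((self.J, self.q))

    def _year_terms(self, Zs, p_fit, w):
        """Per-year score and curvature blocks of the joint objective in u."""
        J, q, yi = self.J, self.q, self.yi
        g = np.empty((J, q))
        H = np.empty((J, q, q))
        resid = self.y - p_fit
        for k in range(q):
            g[:, k] = np.bincount(yi, weights=resid * Zs[:, k], minlength=J)
            for l in range(k, q):
                H[:, k, l] = H[:, l, k] = np.bincount(
                    yi, weights=w * Zs[:, k] * Zs[:, l], minlength=J
                )
        return g, H

    def _penalized(self, offset, Zs, u):
        eta = offset + np.einsum("nq,nq->n", Zs, u[self.yi])
        return _bernoulli_loglik(eta, self.y) - 0.5 * float((u * u).sum()), eta

    def solve_modes(self, offset, sigma, tol=1e-10, max_iter=60):
        Zs = self.Z * sigma
        u = self.u.copy()
        obj, eta = self._penalized(offset, Zs, u)
        for _ in range(max_iter):
            mu = expit(eta)
            w = mu * (1.0 - mu)
            g, H = self._year_terms(Zs, mu, w)
            g -= u
            if np.max(np.abs(g)) < tol:
                break
            H += np.eye(self.q)
            step = np.linalg.solve(H, g[..., None])[..., 0]
            for _ in range(30):
                cand = u + step
                obj_new, eta_new = self._penalized(offset, Zs, cand)
                if obj_new >= obj - 1e-12:
                    break
                step *= 0.5
            u, obj, eta = u + step, obj_new, eta_new
        self.u = u
        return u, eta

    def loglik(self, beta, sigma):
        offset = self.X @ beta
        u, eta = self.solve_modes(offset, sigma)
        Zs = self.Z * sigma
        mu = expit(eta)
        w = mu * (1.0 - mu)
        _, H = self._year_terms(Zs, mu, w)
        H += np.eye(self.q)
        sign, logdet = np.linalg.slogdet(H)
        if np.any(sign <= 0):
            return -np.inf
        ll = _bernoulli_loglik(eta, self.y)
        ll -= 0.5 * float((u * u).sum())
        ll -= 0.5 * float(logdet.sum())
        return ll

    def __call__(self, params):
        beta, sigma = params[: self.p], params[self.p :]
        ll = self.loglik(beta, sigma)
        return np.inf if not np.isfinite(ll) else -ll

    def cov_beta(self, beta, sigma):
        """Covariance of beta from the joint observed information at the mode.

        Profiles the random effects out of the joint (beta, u) information,
        i.e. the Schur complement X'WX - A H^{-1} A'; at sigma = 0 this
        reduces to the plain logistic information.
        """
        offset = self.X @ beta
        u, eta = self.solve_modes(offset, sigma)
        Zs = self.Z * sigma
        mu = expit(eta)
        w = mu * (1.0 - mu)
        info = self.X.T @ (self.X * w[:, None])
        _, H = self._year_terms(Zs, mu, w)
        H += np.eye(self.q)
        # A_j = X_j' W_j Zs_j, accumulated per year
        A = np.empty((self.J, self.p, self.q))
        for a in range(self.p):
            for k in range(self.q):
                A[:, a, k] = np.bincount(
                    self.yi, weights=w * self.X[:, a] * Zs[:, k], minlength=self.J
                )
        correction = np.einsum("jak,jkl,jbl->ab", A, np.linalg.inv(H), A)
        info -= correction
        cov = np.linalg.inv(info + 1e-12 * np.eye(self.p))
        return 0.5 * (cov + cov.T)


def fit_glmm(
    spec: ModelSpec,
    table: CovariateTable,
    fix_sigma: Sequence[float] | None = None,
    max_outer: int = 500,
    gtol: float = 1e-6,
) -> ModelFit:
    """Fit one candidate model by Laplace-approximated maximum likelihood.

    ``fix_sigma`` pins the random-effect standard deviations (e.g. all zeros
    collapses the fit to plain logistic regression); otherwise they are
    estimated under a non-negativity bound.  Non-convergence is reported via
    the ``converged`` flag, never as an exception; a single-class outcome is
    an error.
    """
    if len(table) == 0:
        raise ValueError("empty covariate table")
    X, names, Z, years, yi, y = _design_matrices(table, spec)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError(f"outcome has a single class ({classes.tolist()}); model not identifiable")

    n, p = X.shape
    q = spec.n_random
    J = len(years)
    obj = _LaplaceObjective(X, Z, yi, y, J)

    beta0, ll0, newton_ok = _newton_logistic(X, y)

    if fix_sigma is not None:
        sigma = np.asarray(fix_sigma, dtype=float)
        if sigma.shape != (q,):
            raise ValueError(f"fix_sigma must have length {q} for {spec.random_structure}")
        if np.all(sigma == 0.0):
            beta, loglik, converged = beta0, ll0, newton_ok
        else:
            res = minimize(
                lambda b: -obj.loglik(b, sigma),
                beta0,
                method="L-BFGS-B",
                options={"maxiter": max_outer, "ftol": 1e-13, "gtol": gtol},
            )
            beta, loglik = res.x, -res.fun
            converged = bool(res.success) or float(np.max(np.abs(res.jac))) < 1e-4
    else:
        x0 = np.concatenate([beta0, np.full(q, 0.3)])
        bounds = [(None, None)] * p + [(0.0, None)] * q
        res = minimize(
            obj,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_outer, "ftol": 1e-13, "gtol": gtol},
        )
        beta, sigma = res.x[:p], res.x[p:]
        loglik = -res.fun
        converged = bool(res.success) or float(np.max(np.abs(res.jac))) < 1e-4

    sigma = np.where(sigma < SIGMA_FLOOR, 0.0, sigma)
    separation = bool(np.max(np.abs(beta)) > SEPARATION_BETA)
    if separation:
        logger.warning("possible complete separation in %s (max |beta| > %s)", spec.label, SEPARATION_BETA)

    cov_beta = obj.cov_beta(beta, sigma)
    u, _ = obj.solve_modes(X @ beta, sigma)
    modes = pd.DataFrame(
        u * sigma, index=pd.Index(years, name="year"), columns=list(RANDOM_COLUMNS[:q])
    )

    k = p + q
    return ModelFit(
        spec=spec,
        beta_names=names,
        beta_hat=np.asarray(beta, dtype=float),
        sigma_hat=np.asarray(sigma, dtype=float),
        cov_beta=cov_beta,
        loglik=float(loglik),
        k=k,
        n=n,
        aicc=aicc(float(loglik), k, n),
        converged=bool(converged),
        separation=separation,
        conditional_modes=modes,
    )


def fit_model_space(space: ModelSpace, table: CovariateTable, **kwargs) -> list[ModelFit]:
    """Fit every candidate model in a space on one design table."""
    return [fit_glmm(spec, table, **kwargs) for spec in space]


def predict_survival(
    fit: ModelFit,
    newdata: Mapping[str, float] | pd.DataFrame,
    include_random: bool = False,
    b: Sequence[float] | None = None,
) -> np.ndarray:
    """Inverse-logit survival prediction for new covariate rows.

    ``newdata`` maps covariate names (on the standardized scale used at
    fitting) to scalars or arrays.  With ``include_random`` the year effects
    ``b`` (intercept[, slope on d[, slope on d2]]) are added to the linear
    predictor.
    """
    missing = [name for name in fit.beta_names if name != "intercept" and name not in newdata]
    if missing:
        raise KeyError(f"newdata missing covariates: {missing}")
    eta = np.asarray(fit.beta_hat[0], dtype=float)
    for name, coef in zip(fit.beta_names[1:], fit.beta_hat[1:]):
        eta = eta + coef * np.asarray(newdata[name], dtype=float)
    if include_random:
        if b is None:
            raise ValueError("include_random=True requires year effects b")
        b = np.asarray(b, dtype=float)
        q = len(fit.sigma_hat)
        if b.shape[-1] != q:
            raise ValueError(f"b must supply {q} random terms for {fit.spec.random_structure}")
        eta = eta + b[..., 0]
        if q >= 2:
            eta = eta + b[..., 1] * np.asarray(newdata["d"], dtype=float)
        if q >= 3:
            eta = eta + b[..., 2] * np.asarray(newdata["d2"], dtype=float)
    return expit(eta)
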