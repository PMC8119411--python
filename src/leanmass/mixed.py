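"""A compact REML engine for Gaussian mixed models with i.i.d. blocks.

Fits ``y = X beta + sum_j Z_j u_j + e`` where each random block has
``u_j ~ N(0, sigma2 * theta_j * I)`` and ``e ~ N(0, sigma2 * I)``. The
profiled restricted likelihood is optimised over the log variance ratios
``log(theta_j)``; everything else (beta, sigma2, BLUPs, effective degrees
of freedom, the Bayesian coefficient covariance) follows in closed form.

Both the penalized-spline smooth (whose smoothing parameter is a variance
ratio) and the per-individual random intercept are blocks of this form,
so one engine serves the additive mixed model and the plain mixed model.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

from .errors import ConvergenceError, InsufficientDataError

__all__ = ["MixedFit", "fit_reml"]

_LOG_THETA_MIN = -14.0
_LOG_THETA_MAX = 10.0


@dataclasses.dataclass
class MixedFit:
    """Everything downstream inference needs from one REML fit."""

    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: float
    theta: dict[str, float]  # variance ratios sigma_j^2 / sigma^2
    block_names: tuple[str, ...]
    block_slices: dict[str, slice]  # into the stacked random-coefficient vector
    u: np.ndarray  # BLUPs of the stacked *scaled* coefficients (on sqrt(theta)*Z scale)
    edf: np.ndarray  # per-column effective df over [X | scaled Z]
    cov_coef: np.ndarray  # Bayesian covariance of (beta, u), sigma2 * Ainv
    fitted_fixed: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    reml_loglik: float
    n: int
    p: int

    @property
    def edf_fixed(self) -> np.ndarray:
        return self.edf[: self.p]

    def edf_block(self, name: str) -> float:
        s = self.block_slices[name]
        return float(self.edf[self.p + s.start : self.p + s.stop].sum())

    @property
    def edf_total(self) -> float:
        return float(self.edf.sum())

    def block_sd(self, name: str) -> float:
        return float(np.sqrt(self.sigma2 * self.theta[name]))

    @property
    def residual_sd(self) -> float:
        return float(np.sqrt(self.sigma2))

    def random_contribution(self, name: str, Z_new: np.ndarray) -> np.ndarray:
        """Predicted contribution of block ``name`` on new rows ``Z_new``."""
        s = self.block_slices[name]
        scale = np.sqrt(self.theta[name])
        return scale * (Z_new @ self.u[s])


def _neg_reml(log_theta, y, X, Zs):
    n, p = X.shape
    W = np.hstack([np.sqrt(np.exp(lt)) * Z for lt, Z in zip(log_theta, Zs)])
    q = W.shape[1]
    M = W.T @ W
    M[np.diag_indices(q)] += 1.0
    try:
        cM = cho_factor(M, lower=True)
    except np.linalg.LinAlgError:
        return 1e12
    logdet_M = 2.0 * np.log(np.diag(cM[0])).sum()

    def vinv(A):
        return A - W @ cho_solve(cM, W.T @ A)

    Xv = vinv(X)
    yv = vinv(y)
    G = X.T @ Xv
    c = X.T @ yv
    try:
        cG = cho_factor(G, lower=True)
    except np.linalg.LinAlgError:
        return 1e12
    beta = cho_solve(cG, c)
    quad = float(y @ yv - c @ beta)
    if quad <= 0:
        return 1e12
    logdet_G = 2.0 * np.log(np.diag(cG[0])).sum()
    return (n - p) * np.log(quad) + logdet_M + logdet_G


def fit_reml(
    y: np.ndarray,
    X: np.ndarray,
    blocks: dict[str, np.ndarray],
    max_iter: int = 200,
) -> MixedFit:
    """Fit the mixed model by profiled REML.

    Parameters
    ----------
    y, X : response vector and fixed-effects design (full column rank).
    blocks : mapping name -> Z matrix of a random block with i.i.d.
        coefficients. Order is preserved.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise InsufficientDataError(f"need n > p; got n={n}, p={p}")
    names = tuple(blocks)
    Zs = [np.asarray(blocks[k], dtype=float) for k in names]

    x0 = np.zeros(len(Zs))
    bounds = [(_LOG_THETA_MIN, _LOG_THETA_MAX)] * len(Zs)
    res = optimize.minimize(
        _neg_reml,
        x0,
        args=(y, X, Zs),
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "ftol": 1e-13, "gtol": 1e-9},
    )
    # Polish with a derivative-free pass: the numeric L-BFGS-B gradient can
    # stall short of the optimum, and relevel invariance needs tight theta.
    res2 = optimize.minimize(
        _neg_reml,
        np.clip(res.x, _LOG_THETA_MIN, _LOG_THETA_MAX),
        args=(y, X, Zs),
        method="Nelder-Mead",
        options={"maxiter": 4 * max_iter, "xatol": 1e-10, "fatol": 1e-12},
    )
    if res2.fun <= res.fun:
        res = res2
    if not np.isfinite(res.fun):
        raise ConvergenceError(f"REML optimisation failed: {res.message}")
    log_theta = np.clip(res.x, _LOG_THETA_MIN, _LOG_THETA_MAX)
    theta = np.exp(log_theta)

    # Closed-form quantities at the optimum, via the augmented
    # penalized-least-squares system A = C'C + D with D = blkdiag(0, I).
    W = np.hstack([np.sqrt(t) * Z for t, Z in zip(theta, Zs)])
    q = W.shape[1]
    C = np.hstack([X, W])
    CtC = C.T @ C
    A = CtC.copy()
    A[p:, p:][np.diag_indices(q)] += 1.0
    cA = cho_factor(A, lower=True)
    coef = cho_solve(cA, C.T @ y)
    beta, u = coef[:p], coef[p:]
    Ainv = cho_solve(cA, np.eye(p + q))
    edf = np.einsum("ij,ji->i", Ainv, CtC)

    fitted = C @ coef
    fitted_fixed = X @ beta
    resid = y - fitted

    # sigma2 and the REML loglik from the profiled criterion pieces.
    M = W.T @ W
    M[np.diag_indices(q)] += 1.0
    cM = cho_factor(M, lower=True)
    logdet_M = 2.0 * np.log(np.diag(cM[0])).sum()
    yv = y - W @ cho_solve(cM, W.T @ y)
    Xv = X - W @ cho_solve(cM, W.T @ X)
    G = X.T @ Xv
    cG = cho_factor(G, lower=True)
    logdet_G = 2.0 * np.log(np.diag(cG[0])).sum()
    quad = float(y @ yv - (X.T @ yv) @ cho_solve(cG, X.T @ yv))
    sigma2 = quad / (n - p)
    reml_loglik = -0.5 * (
        (n - p) * (np.log(2.0 * np.pi * sigma2) + 1.0) + logdet_M + logdet_G
    )
    cov_beta = sigma2 * cho_solve(cG, np.eye(p))

    slices = {}
    start = 0
    for name, Z in zip(names, Zs):
        slices[name] = slice(start, start + Z.shape[1])
        start += Z.shape[1]

    return MixedFit(
        beta=beta,
        cov_beta=cov_beta,
        sigma2=float(sigma2),
        theta={name: float(t) for name, t in zip(names, theta)},
        block_names=names,
        block_slices=slices,
        u=u,
        edf=edf,
        cov_coef=sigma2 * Ainv,
        fitted_fixed=fitted_fixed,
        fitted=fitted,
        residuals=resid,
        reml_loglik=float(reml_loglik),
        n=n,
        p=p,
    )
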