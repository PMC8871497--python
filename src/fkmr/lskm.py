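"""Least-squares kernel machine via its linear mixed-model representation.

For fixed kernel Gram matrix K the penalized least-squares problem

    min_{beta, alpha}  (1/2n) ||Y - X beta - K alpha||^2 + (lambda1/2) alpha' K alpha

has a closed-form solution, and its smoothing parameter corresponds to the
variance-component ratio of the mixed model Y = X beta + h + eps with
h ~ N(0, tau K), eps ~ N(0, sigma^2 I):  lambda1 = sigma^2 / (n tau).  REML
estimation of (tau, sigma^2) therefore tunes lambda1 without cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = ["LskmFit", "solve_fixed_lambda", "reml_fit", "predict_lskm",
           "DegenerateKernelWarning"]

JITTER = 1e-10
LOG_THETA_BOUNDS = (-12.0, 12.0)


class DegenerateKernelWarning(UserWarning):
    """K is (numerically) a multiple of the identity: tau and sigma^2 are
    jointly unidentifiable, or the fit sits on the tau = 0 boundary."""


@dataclass
class LskmFit:
    beta: np.ndarray
    alpha: np.ndarray
    h_hat: np.ndarray
    tau: float
    sigma2: float
    lambda1: float
    reml_loglik: float
    converged: bool
    no_kernel_effect: bool = False
    #: restricted-likelihood-ratio statistic for tau = 0 (boundary test);
    #: under the null its distribution is a 50:50 mix of 0 and chi-square(1).
    lrt_kernel: float = 0.0


def _as_design(X: np.ndarray | None, n: int) -> np.ndarray:
    if X is None:
        return np.empty((n, 0))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != n:
        X = X.T
    if X.shape[0] != n:
        raise ValueError("X row count does not match Y")
    return X


def solve_fixed_lambda(Y: np.ndarray, X: np.ndarray | None, K: np.ndarray,
                       lambda1: float) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form (beta, alpha) at fixed (gamma, lambda1).

    alpha = (K + n lambda1 I)^{-1} (Y - X beta) and beta solves the profiled
    normal equations X' M (Y - X beta) = 0 with M = (K + n lambda1 I)^{-1},
    i.e. generalized least squares under V proportional to K + n lambda1 I.
    """
    if lambda1 <= 0:
        raise ValueError("lambda1 must be positive")
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    X = _as_design(X, n)
    q = X.shape[1]
    if q and np.linalg.matrix_rank(X) < q:
        raise np.linalg.LinAlgError("X is rank deficient")
    A = K + (n * lambda1 + JITTER) * np.eye(n)
    if q:
        MX = np.linalg.solve(A, X)
        MY = np.linalg.solve(A, Y)
        beta = np.linalg.solve(X.T @ MX, X.T @ MY)
        alpha = MY - MX @ beta
    else:
        beta = np.empty(0)
        alpha = np.linalg.solve(A, Y)
    return beta, alpha


def reml_fit(Y: np.ndarray, X: np.ndarray | None, K: np.ndarray,
             eig: tuple[np.ndarray, np.ndarray] | None = None) -> LskmFit:
    """REML estimation of (tau, sigma^2) by 1-D search over theta = tau/sigma^2.

    The kernel matrix is eigendecomposed once; the restricted likelihood is
    then optimized over log(theta) on a bounded interval with Brent's method.
    A precomputed eigendecomposition ``eig = (d, U)`` may be supplied.
    """
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    X = _as_design(X, n)
    q = X.shape[1]
    if n <= q:
        raise ValueError("need more subjects than fixed-effect columns")

    if eig is None:
        d, U = np.linalg.eigh(K + JITTER * np.eye(n))
    else:
        d, U = eig
    d = np.clip(d, 0.0, None)

    if d[-1] - d[0] <= 1e-8 * max(d[-1], 1.0):
        warnings.warn("kernel matrix is numerically a multiple of the identity; "
                      "tau and sigma^2 are not separately identifiable",
                      DegenerateKernelWarning)

    yt = U.T @ Y
    Xt = U.T @ X

    def profiled(u: float) -> tuple[float, np.ndarray, float]:
        theta = np.exp(u)
        w = theta * d + 1.0
        if q:
            Xw = Xt / w[:, None]
            A = Xt.T @ Xw
            beta = np.linalg.solve(A, Xw.T @ yt)
            r = yt - Xt @ beta
            _, logdet_A = np.linalg.slogdet(A)
        else:
            beta = np.empty(0)
            r = yt
            logdet_A = 0.0
        s2 = float(r @ (r / w)) / (n - q)
        s2 = max(s2, 1e-300)
        crit = (n - q) * np.log(s2) + float(np.sum(np.log(w))) + logdet_A
        return crit, beta, s2

    res = minimize_scalar(lambda u: profiled(u)[0], bounds=LOG_THETA_BOUNDS,
                          method="bounded", options={"xatol": 1e-8})
    u_hat = float(res.x)
    crit, beta, sigma2 = profiled(u_hat)
    crit_null = profiled(-np.inf)[0]  # theta = 0: no kernel effect
    lrt = max(0.0, crit_null - crit)
    theta = np.exp(u_hat)
    tau = theta * sigma2

    no_kernel_effect = u_hat <= LOG_THETA_BOUNDS[0] + 1e-3 or sigma2 < 1e-12
    if no_kernel_effect:
        warnings.warn("REML variance-component fit is at the boundary: "
                      "no kernel effect detected", DegenerateKernelWarning)

    w = theta * d + 1.0
    r_rot = yt - Xt @ beta if q else yt
    alpha = theta * (U @ (r_rot / w))
    h_hat = K @ alpha
    lambda1 = sigma2 / (n * tau) if tau > 0 else np.inf
    # Restricted log-likelihood up to an additive constant.
    reml_ll = -0.5 * (crit + (n - q))
    return LskmFit(beta=beta, alpha=alpha, h_hat=h_hat, tau=tau, sigma2=sigma2,
                   lambda1=lambda1, reml_loglik=reml_ll, converged=bool(res.success),
                   no_kernel_effect=no_kernel_effect, lrt_kernel=lrt)


def predict_lskm(fit: LskmFit, X_new: np.ndarray | None,
                 K_cross: np.ndarray) -> np.ndarray:
    """Out-of-sample prediction: yhat = X_new beta + K_cross alpha."""
    K_cross = np.atleast_2d(np.asarray(K_cross, dtype=float))
    if K_cross.shape[1] != fit.alpha.shape[0]:
        raise ValueError("K_cross column count must match training size")
    pred = K_cross @ fit.alpha
    if fit.beta.size:
        X_new = _as_design(X_new, K_cross.shape[0])
        pred = pred + X_new @ fit.beta
    return pred
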