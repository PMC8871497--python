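"""Functional kernel machine regression with garrote-based feature selection.

The model is y_i = x_i' beta + h(gamma o z_i) + eps_i, with h in the RKHS of
a Gaussian kernel evaluated on garrote-scaled FPC features gamma o z.  The
penalized objective (in its representer form) is

    J2(alpha, beta, gamma) = (1/2n) ||Y - X beta - K(gamma) alpha||^2
                             + (lambda1/2) alpha' K(gamma) alpha
                             + lambda2 rho(gamma; delta),

minimized by alternating two steps: (i) at fixed gamma, the closed-form
kernel-machine solve (with lambda1 tuned by REML through the mixed-model
equivalence), and (ii) at fixed (beta, alpha, lambda1), a proximal
Gauss-Newton update of gamma.  For step (ii), minimizing J2 over gamma is
equivalent to minimizing

    (1/2n) ||F(gamma) - Ytil||^2 + lambda2 rho(gamma),
    F(gamma) = K(gamma) alpha,   Ytil = Y - X beta - (n lambda1 / 2) alpha,

and linearizing F at a reference point turns each inner iteration into a
standard sparse-group penalized least-squares problem.  Step-halving toward
the reference point guarantees the descent of the exact objective.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .kernels import KernelSpec, grad_F, kernel_cross, kernel_matrix
from .lskm import DegenerateKernelWarning, reml_fit, solve_fixed_lambda
from .penalties import (PenaltySpec, make_lambda_path, penalty_value,
                        solve_penalized_ls)

__all__ = ["FKMRRegressor", "objective_J2", "linearize", "update_gamma",
           "selected_features", "PENALTY_ALIASES"]

PENALTY_ALIASES = {
    "lasso": "lasso",
    "glasso": "group_lasso",
    "group_lasso": "group_lasso",
    "sgl": "sgl",
    "mcp": "mcp",
    "gmcp": "group_mcp",
    "group_mcp": "group_mcp",
}

LAMBDA1_CAP = 1e8  # stands in for lambda1 = +inf at the tau = 0 boundary


def _design_parts(X, group_sizes):
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D: [scalar covariates | features]")
    s = int(sum(group_sizes))
    q = X.shape[1] - s
    if q < 0:
        raise ValueError("group sizes exceed the number of columns in X")
    return X[:, :q], X[:, q:], q


def objective_J2(Y, X, Z, beta, alpha, gamma, lambda1, lambda2, spec,
                 kspec: KernelSpec, K: np.ndarray | None = None) -> float:
    """The penalized representer objective J2 (smaller is better)."""
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    if K is None:
        K = kernel_matrix(Z, gamma, kspec)
    resid = Y - K @ alpha
    if beta is not None and np.size(beta):
        resid = resid - np.asarray(X, dtype=float) @ beta
    pen = penalty_value(gamma, spec, lambda2) if lambda2 > 0 else 0.0
    return (0.5 * float(resid @ resid) / n
            + 0.5 * lambda1 * float(alpha @ (K @ alpha)) + pen)


def _pseudo_response(Y, X, beta, alpha, lambda1):
    """Ytil = Y - X beta - (n lambda1 / 2) alpha, the fixed target of the
    gamma subproblem."""
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    out = Y - 0.5 * n * lambda1 * alpha
    if beta is not None and np.size(beta):
        out = out - np.asarray(X, dtype=float) @ beta
    return out


def linearize(Y, X, Z, beta, alpha, gamma_ref, lambda1, kspec: KernelSpec,
              K: np.ndarray | None = None):
    """First-order expansion of F(gamma) = K(gamma) alpha at gamma_ref.

    Returns the (n x s) gradient design and the linearized response
    Ytil - F(gamma_ref) + grad F(gamma_ref) gamma_ref, so the gamma
    subproblem becomes penalized least squares of response on design.
    """
    alpha = np.asarray(alpha, dtype=float)
    if not np.all(np.isfinite(alpha)):
        raise ValueError("non-finite alpha in linearization")
    if K is None:
        K = kernel_matrix(Z, gamma_ref, kspec)
    design = grad_F(Z, gamma_ref, alpha, kspec, K=K)
    response = _pseudo_response(Y, X, beta, alpha, lambda1) - K @ alpha \
        + design @ gamma_ref
    return design, response


def update_gamma(Y, X, Z, beta, alpha, gamma0, lambda1, lambda2, spec,
                 kspec: KernelSpec, max_inner: int = 50, inner_tol: float = 1e-4,
                 max_halvings: int = 30, K0: np.ndarray | None = None):
    """Proximal Gauss-Newton update of gamma at fixed (beta, alpha, lambda1).

    Each iteration linearizes F, solves the sparse-group problem at lambda2,
    then halves the step toward the reference point until the exact
    subproblem objective does not increase.

    Returns (gamma, objective trace, stalled flag, K at gamma, final objective).
    """
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    gamma = np.asarray(gamma0, dtype=float).copy()
    ytil = _pseudo_response(Y, X, beta, alpha, lambda1)

    def exact_obj(g, K=None):
        if K is None:
            K = kernel_matrix(Z, g, kspec)
        r = K @ alpha - ytil
        return 0.5 * float(r @ r) / n + penalty_value(g, spec, lambda2), K

    obj, K = exact_obj(gamma, K0)
    trace = [obj]
    stalled = False
    for _ in range(max_inner):
        design, response = linearize(Y, X, Z, beta, alpha, gamma, lambda1,
                                     kspec, K=K)
        cand, _, _ = solve_penalized_ls(design, response, spec, float(lambda2),
                                        x0=gamma)
        accepted = False
        for _h in range(max_halvings + 1):
            obj_c, K_c = exact_obj(cand)
            if obj_c <= obj + 1e-12 * (1.0 + abs(obj)):
                accepted = True
                break
            cand = 0.5 * (cand + gamma)
        if not accepted:
            stalled = True
            break
        rel = np.linalg.norm(cand - gamma) / (1.0 + np.linalg.norm(gamma))
        gamma, obj, K = cand, obj_c, K_c
        trace.append(obj)
        if rel < inner_tol:
            break
    return gamma, trace, stalled, K, obj


def selected_features(gamma: np.ndarray, tol: float,
                      group_sizes: tuple[int, ...]):
    """Indices of features with |gamma_j| > tol and of groups containing any."""
    if tol <= 0:
        raise ValueError("selection tolerance must be positive")
    gamma = np.asarray(gamma, dtype=float)
    feat = np.flatnonzero(np.abs(gamma) > tol)
    edges = np.concatenate([[0], np.cumsum(group_sizes)])
    groups = [g for g in range(len(group_sizes))
              if np.any((feat >= edges[g]) & (feat < edges[g + 1]))]
    return feat, np.asarray(groups, dtype=int)


class FKMRRegressor(BaseEstimator, RegressorMixin):
    """Kernel machine regression with bi-level feature selection.

    The design matrix passed to :meth:`fit` is ``[scalar covariates |
    features]``: the trailing ``sum(group_sizes)`` columns are the grouped
    (FPC) features entering the kernel; any leading columns are modeled
    linearly.  The Gaussian-kernel bandwidth denominator is fixed at the
    total feature count.

    Parameters
    ----------
    group_sizes : tuple of int
        Contiguous feature-block sizes, one per functional predictor.
    penalty : {'lasso', 'glasso', 'sgl', 'mcp', 'gmcp'}
        Penalty on the scaling vector gamma.
    delta : float, default 0.05
        SGL mixing weight on the elementwise l1 part (0 = group lasso).
    algorithm : {1, 2}, default 2
        2 = fast operational scheme (REML once, one CV-tuned gamma update,
        final kernel-machine re-solve); 1 = full alternation with
        cross-validation over a (lambda1, lambda2) grid.
    lambda2 : float, optional
        Fixed penalty level for the gamma update; cross-validated if None.
    cv : int, default 5
        Folds for internal cross-validation.
    random_state : int, optional
        Seed for fold assignment.

    Attributes
    ----------
    beta_, alpha_, gamma_ : fitted coefficients (gamma_ reported as |gamma|).
    lambda1_, lambda2_, tau_, sigma2_ : tuning/variance parameters.
    objective_trace_ : J2 values along the accepted optimization steps.
    selected_features_, selected_groups_ : integer index arrays.
    """

    def __init__(self, group_sizes=None, penalty="sgl", delta=0.05, mcp_a=3.0,
                 algorithm=2, lambda2=None, lambda1_grid=None, lambda2_grid=None,
                 n_lambda=40, lambda_ratio=1e-5, cv=5, max_outer=25, max_inner=50,
                 outer_tol=1e-4, inner_tol=1e-4, j2_tol=1e-6, selection_tol=1e-6,
                 random_state=None):
        self.group_sizes = group_sizes
        self.penalty = penalty
        self.delta = delta
        self.mcp_a = mcp_a
        self.algorithm = algorithm
        self.lambda2 = lambda2
        self.lambda1_grid = lambda1_grid
        self.lambda2_grid = lambda2_grid
        self.n_lambda = n_lambda
        self.lambda_ratio = lambda_ratio
        self.cv = cv
        self.max_outer = max_outer
        self.max_inner = max_inner
        self.outer_tol = outer_tol
        self.inner_tol = inner_tol
        self.j2_tol = j2_tol
        self.selection_tol = selection_tol
        self.random_state = random_state

    # ------------------------------------------------------------------ #

    def _spec(self) -> PenaltySpec:
        family = PENALTY_ALIASES.get(self.penalty)
        if family is None:
            raise ValueError(f"unknown penalty {self.penalty!r}")
        groups = tuple(self.group_sizes) if self.group_sizes else ()
        if family in ("lasso", "mcp") and not groups:
            groups = ()
        return PenaltySpec(family=family, delta=self.delta, mcp_a=self.mcp_a,
                           groups=groups)

    def fit(self, X, y):
        if self.group_sizes is None:
            raise ValueError("group_sizes must be provided")
        y = np.asarray(y, dtype=float).ravel()
        Xc, Z, q = _design_parts(X, self.group_sizes)
        if Z.shape[0] != y.shape[0]:
            raise ValueError("X and y disagree on the number of subjects")
        self._spec_ = self._spec()
        self._kspec_ = KernelSpec(bandwidth_denominator=float(Z.shape[1]))
        self._q_ = q
        self.Z_train_ = Z
        self.n_features_in_ = X.shape[1]
        rng = np.random.default_rng(self.random_state)
        if self.algorithm == 2:
            self._fit_algorithm2(y, Xc, Z, rng)
        elif self.algorithm == 1:
            self._fit_algorithm1(y, Xc, Z, rng)
        else:
            raise ValueError("algorithm must be 1 or 2")
        self.gamma_ = np.abs(self.gamma_)
        feat, grp = selected_features(self.gamma_, self.selection_tol,
                                      tuple(self.group_sizes))
        self.selected_features_ = feat
        self.selected_groups_ = grp
        return self

    # ------------------------------------------------------------------ #

    def _select_lambda2(self, y, Xc, Z, rng):
        """Validation-split tuning of lambda2 with faithful refits.

        For each candidate lambda2, the full pipeline is re-run on a
        training subsplit — kernel-machine solve at gamma = 1, proximal
        Gauss-Newton gamma update (warm-started along the path), REML
        re-solve at the updated gamma — and scored by prediction MSE of the
        held-out outcomes.  Tuning on the linearized least-squares problem
        alone is not honest here: its design and response both depend on
        alpha fitted to all subjects, which leaks the held-out outcomes into
        every fold.
        """
        spec, kspec = self._spec_, self._kspec_
        n, s = Z.shape
        Xq = Xc if self._q_ else None
        perm = rng.permutation(n)
        n_val = max(n // 5, 1)
        val, sub = perm[:n_val], perm[n_val:]
        y_s, Z_s = y[sub], Z[sub]
        Xc_s = Xc[sub] if self._q_ else Xc
        Xq_s = Xc_s if self._q_ else None

        K_s = kernel_matrix(Z_s, np.ones(s), kspec)
        eig_s = np.linalg.eigh(K_s + 1e-10 * np.eye(len(sub)))
        fit_s = reml_fit(y_s, Xq_s, K_s, eig=eig_s)
        lam1_s = min(fit_s.lambda1, LAMBDA1_CAP)
        design, response = linearize(y_s, Xc_s, Z_s, fit_s.beta, fit_s.alpha,
                                     np.ones(s), lam1_s, kspec, K=K_s)
        if self.lambda2_grid is not None:
            path = np.asarray(self.lambda2_grid, dtype=float)
        else:
            path = make_lambda_path(design, response, spec,
                                    min(self.n_lambda, 12), self.lambda_ratio)
        # Each candidate restarts from gamma = 1: exact zeros are absorbing
        # under the Gauss-Newton map (the gradient carries a factor gamma_j),
        # so warm-starting down the path would lock features out.
        errs = np.full(path.size, np.inf)
        for i, lam2 in enumerate(path):
            gamma_w, _, _, K_g, _ = update_gamma(
                y_s, Xc_s, Z_s, fit_s.beta, fit_s.alpha, np.ones(s), lam1_s,
                float(lam2), spec, kspec, max_inner=min(self.max_inner, 15),
                inner_tol=self.inner_tol, K0=K_s)
            eig_g = np.linalg.eigh(K_g + 1e-10 * np.eye(len(sub)))
            fit_g = reml_fit(y_s, Xq_s, K_g, eig=eig_g)
            pred = kernel_cross(Z[val], Z_s, gamma_w, kspec) @ fit_g.alpha
            if self._q_:
                pred = pred + Xc[val] @ fit_g.beta
            errs[i] = float(np.mean((y[val] - pred) ** 2))
            # Past the minimum the error rises steeply into the overfit
            # regime; stop once it has doubled.
            if errs[i] > 2.0 * errs.min() and i > int(np.argmin(errs)):
                break
        # Parsimony rule: the largest lambda2 whose validation error is
        # within 2% of the minimum (near-ties favor the sparser model).
        best = float(errs.min())
        idx = int(np.flatnonzero(errs <= 1.02 * best)[0])
        return float(path[idx]), path, errs

    def _profile_gamma_scale(self, y, Xc, Z, gamma, rng):
        """REML-profiled global scale of the fitted scaling vector.

        The proximal Gauss-Newton update determines the support and the
        relative sizes of gamma but tends to a stationary point near the
        flat-kernel basin it starts from; the overall sharpness of the
        kernel along the ray c * gamma is a one-dimensional lengthscale
        parameter that the restricted likelihood identifies cleanly.  The
        profile is evaluated on a training subsample (the optimum is stable
        in n), then the best grid point is returned.  The support of gamma
        and hence the selection sets are unchanged.
        """
        if not np.any(np.abs(gamma) > self.selection_tol):
            return 1.0
        kspec = self._kspec_
        n = len(y)
        idx = rng.permutation(n)[:min(n, 400)]
        y_s = y[idx]
        Z_s = Z[idx]
        Xq_s = Xc[idx] if self._q_ else None
        grid = np.geomspace(1.0, 32.0, 11)
        best_c, best_ll = 1.0, -np.inf
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateKernelWarning)
            for c in grid:
                K = kernel_matrix(Z_s, c * gamma, kspec)
                fit = reml_fit(y_s, Xq_s, K)
                if fit.reml_loglik > best_ll and not fit.no_kernel_effect:
                    best_c, best_ll = float(c), fit.reml_loglik
        return best_c

    def _fit_algorithm2(self, y, Xc, Z, rng):
        spec, kspec = self._spec_, self._kspec_
        s = Z.shape[1]
        gamma = np.ones(s)
        K1 = kernel_matrix(Z, gamma, kspec)
        eig1 = np.linalg.eigh(K1 + 1e-10 * np.eye(len(y)))
        fit0 = reml_fit(y, Xc if self._q_ else None, K1, eig=eig1)
        lam1 = min(fit0.lambda1, LAMBDA1_CAP)
        beta, alpha = fit0.beta, fit0.alpha

        # Boundary restricted-LRT for the kernel variance component: under
        # the null (tau = 0) the statistic is a 50:50 mix of 0 and
        # chi-square(1); 2.71 is its upper 5% point.  Without evidence of a
        # kernel effect the garrote zeroes every feature.
        if self.lambda2 is None and fit0.lrt_kernel < 2.71:
            self.gamma_ = np.zeros(s)
            self.beta_ = fit0.beta
            self.alpha_ = np.zeros(len(y))
            self.lambda1_ = lam1
            self.lambda2_ = None
            self.tau_ = 0.0
            self.sigma2_ = fit0.sigma2
            self.objective_trace_ = np.asarray(
                [objective_J2(y, Xc, Z, fit0.beta, self.alpha_, self.gamma_,
                              lam1, 0.0, spec, kspec)])
            self.n_outer_iterations_ = 0
            self.converged_ = True
            return

        if self.lambda2 is not None:
            lam2 = float(self.lambda2)
        else:
            lam2, _, _ = self._select_lambda2(y, Xc, Z, rng)

        j2_start = objective_J2(y, Xc, Z, beta, alpha, gamma, lam1, lam2,
                                spec, kspec, K=K1)
        gamma, g_trace, stalled, K2, _ = update_gamma(
            y, Xc, Z, beta, alpha, gamma, lam1, lam2, spec, kspec,
            max_inner=self.max_inner, inner_tol=self.inner_tol, K0=K1)
        # The gamma subproblem objective differs from J2 by a gamma-constant
        # offset; report the trace on the J2 scale.
        offset = j2_start - g_trace[0]
        trace = [j2_start] + [v + offset for v in g_trace[1:]]

        beta_d, alpha_d = solve_fixed_lambda(y, Xc if self._q_ else None, K2, lam1)
        trace.append(objective_J2(y, Xc, Z, beta_d, alpha_d, gamma, lam1, lam2,
                                  spec, kspec, K=K2))
        # Final kernel-machine re-solve: REML refresh of (lambda1, beta,
        # alpha) at the updated gamma, with the global kernel scale profiled
        # by REML as part of the variance-component estimation.
        scale = self._profile_gamma_scale(y, Xc, Z, gamma, rng)
        if scale != 1.0:
            gamma = scale * gamma
            K2 = kernel_matrix(Z, gamma, kspec)
        fit2 = reml_fit(y, Xc if self._q_ else None, K2)

        self.beta_ = fit2.beta
        self.alpha_ = fit2.alpha
        self.gamma_ = gamma
        self.lambda1_ = min(fit2.lambda1, LAMBDA1_CAP)
        self.lambda2_ = lam2
        self.tau_ = fit2.tau
        self.sigma2_ = fit2.sigma2
        self.objective_trace_ = np.asarray(trace)
        self.n_outer_iterations_ = 1
        self.converged_ = not stalled

    def _fit_algorithm1(self, y, Xc, Z, rng):
        spec, kspec = self._spec_, self._kspec_
        n, s = Z.shape
        Xq = Xc if self._q_ else None

        if self.lambda1_grid is not None:
            grid1 = np.asarray(self.lambda1_grid, dtype=float)
        else:
            K1 = kernel_matrix(Z, np.ones(s), kspec)
            anchor = min(reml_fit(y, Xq, K1).lambda1, LAMBDA1_CAP)
            grid1 = np.unique(np.append(np.geomspace(1e-4, 10.0, 7), anchor))
        if self.lambda2_grid is not None:
            grid2 = np.asarray(self.lambda2_grid, dtype=float)
        else:
            K1 = kernel_matrix(Z, np.ones(s), kspec)
            fit0 = reml_fit(y, Xq, K1)
            design, response = linearize(y, Xc, Z, fit0.beta, fit0.alpha,
                                         np.ones(s),
                                         min(fit0.lambda1, LAMBDA1_CAP),
                                         kspec, K=K1)
            grid2 = make_lambda_path(design, response, spec,
                                     min(self.n_lambda, 10), self.lambda_ratio)
        if grid1.size == 0 or grid2.size == 0:
            raise ValueError("lambda grids must be nonempty")

        pairs = [(l1, l2) for l1 in grid1 for l2 in grid2]
        if len(pairs) > 1:
            perm = rng.permutation(n)
            folds = np.array_split(perm, self.cv)
            cv_err = np.zeros(len(pairs))
            for f_idx, val in enumerate(folds):
                mask = np.ones(n, dtype=bool)
                mask[val] = False
                for p_idx, (l1, l2) in enumerate(pairs):
                    b, a, g, _ = self._alternate(y[mask], Xc[mask], Z[mask],
                                                 l1, l2)
                    pred = kernel_cross(Z[val], Z[mask], g, kspec) @ a
                    if self._q_:
                        pred = pred + Xc[val] @ b
                    cv_err[p_idx] += float(np.mean((y[val] - pred) ** 2))
            best = pairs[int(np.argmin(cv_err))]
        else:
            best = pairs[0]

        lam1, lam2 = best
        beta, alpha, gamma, trace = self._alternate(y, Xc, Z, lam1, lam2)
        scale = self._profile_gamma_scale(y, Xc, Z, gamma, rng)
        gamma = scale * gamma
        fit_v = reml_fit(y, Xq, kernel_matrix(Z, gamma, kspec))
        self.beta_ = fit_v.beta
        self.alpha_ = fit_v.alpha
        self.gamma_ = gamma
        self.lambda1_ = lam1
        self.lambda2_ = lam2
        self.tau_ = fit_v.tau
        self.sigma2_ = fit_v.sigma2
        self.objective_trace_ = np.asarray(trace)

    def _alternate(self, y, Xc, Z, lam1, lam2):
        """Alternate the kernel-machine solve and the gamma update at a fixed
        (lambda1, lambda2) pair; J2 is non-increasing across both steps."""
        spec, kspec = self._spec_, self._kspec_
        Xq = Xc if self._q_ else None
        s = Z.shape[1]
        gamma = np.ones(s)
        trace: list[float] = []
        K = kernel_matrix(Z, gamma, kspec)
        converged = False
        for it in range(self.max_outer):
            beta, alpha = solve_fixed_lambda(y, Xq, K, lam1)
            j2 = objective_J2(y, Xc, Z, beta, alpha, gamma, lam1, lam2, spec,
                              kspec, K=K)
            trace.append(j2)
            gamma_new, g_trace, _stalled, K, _ = update_gamma(
                y, Xc, Z, beta, alpha, gamma, lam1, lam2, spec, kspec,
                max_inner=self.max_inner, inner_tol=self.inner_tol, K0=K)
            j2_new = objective_J2(y, Xc, Z, beta, alpha, gamma_new, lam1, lam2,
                                  spec, kspec, K=K)
            trace.append(j2_new)
            rel_g = (np.linalg.norm(gamma_new - gamma)
                     / (1.0 + np.linalg.norm(gamma)))
            rel_j = abs(j2 - j2_new) / (1.0 + abs(j2))
            gamma = gamma_new
            if rel_g < self.outer_tol and rel_j < self.j2_tol:
                converged = True
                break
        beta, alpha = solve_fixed_lambda(y, Xq, K, lam1)
        trace.append(objective_J2(y, Xc, Z, beta, alpha, gamma, lam1, lam2,
                                  spec, kspec, K=K))
        self.n_outer_iterations_ = it + 1
        self.converged_ = converged
        return beta, alpha, gamma, trace

    # ------------------------------------------------------------------ #

    def predict(self, X):
        check_is_fitted(self, "gamma_")
        Xc, Z, _ = _design_parts(X, self.group_sizes)
        pred = kernel_cross(Z, self.Z_train_, self.gamma_, self._kspec_) \
            @ self.alpha_
        if self._q_:
            pred = pred + Xc @ self.beta_
        return pred

    def predict_h(self, X):
        """Kernel-machine part of the prediction (excludes the linear term)."""
        check_is_fitted(self, "gamma_")
        _, Z, _ = _design_parts(X, self.group_sizes)
        return kernel_cross(Z, self.Z_train_, self.gamma_, self._kspec_) \
            @ self.alpha_
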