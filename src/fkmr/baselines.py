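"""Penalized linear-model baselines on the FPC features.

These fit y on the scalar covariates plus all probit FPC features under the
same penalty families as the kernel machine, assuming a linear functional
relationship.  Feature columns are standardized before penalization (the
usual convention for lasso-type linear models); scalar covariates and the
intercept are never penalized.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .fkmr import PENALTY_ALIASES, _design_parts, selected_features
from .penalties import PenaltySpec, cv_lambda, make_lambda_path, solve_penalized_ls

__all__ = ["PenalizedLinearModel"]


class PenalizedLinearModel(BaseEstimator, RegressorMixin):
    """Linear model with a (sparse-)group penalty on the feature block.

    The design is ``[scalar covariates | features]`` as in
    :class:`~fkmr.fkmr.FKMRRegressor`; the penalty level is chosen by K-fold
    cross-validation along a log-spaced path.
    """

    def __init__(self, group_sizes=None, penalty="sgl", delta=0.05, mcp_a=3.0,
                 n_lambda=100, lambda_ratio=1e-3, cv=5, standardize=True,
                 selection_tol=1e-8, random_state=None):
        self.group_sizes = group_sizes
        self.penalty = penalty
        self.delta = delta
        self.mcp_a = mcp_a
        self.n_lambda = n_lambda
        self.lambda_ratio = lambda_ratio
        self.cv = cv
        self.standardize = standardize
        self.selection_tol = selection_tol
        self.random_state = random_state

    def fit(self, X, y):
        if self.group_sizes is None:
            raise ValueError("group_sizes must be provided")
        y = np.asarray(y, dtype=float).ravel()
        Xc, Z, q = _design_parts(X, self.group_sizes)
        family = PENALTY_ALIASES.get(self.penalty)
        if family is None:
            raise ValueError(f"unknown penalty {self.penalty!r}")
        spec = PenaltySpec(family=family, delta=self.delta, mcp_a=self.mcp_a,
                           groups=tuple(self.group_sizes))

        if self.standardize:
            mu = Z.mean(axis=0)
            sd = Z.std(axis=0)
            sd[sd == 0] = 1.0
        else:
            mu = np.zeros(Z.shape[1])
            sd = np.ones(Z.shape[1])
        Zs = (Z - mu) / sd
        unpen = np.hstack([np.ones((len(y), 1)), Xc]) if q else \
            np.ones((len(y), 1))

        rng = np.random.default_rng(self.random_state)
        path = make_lambda_path(Zs, y - y.mean(), spec, self.n_lambda,
                                self.lambda_ratio)
        lam, cv_err = cv_lambda(Zs, y, spec, folds=self.cv, lambda_path=path,
                                rng=rng, unpenalized=unpen)
        coef_s, free, _ = solve_penalized_ls(Zs, y, spec, lam, unpenalized=unpen)

        self.lambda_ = lam
        self.cv_errors_ = cv_err
        self.coef_ = coef_s / sd
        self.intercept_ = float(free[0]) - float((self.coef_ * mu).sum())
        self.beta_ = free[1:]
        self._q_ = q
        self._mu_, self._sd_ = mu, sd
        feat, grp = selected_features(coef_s, self.selection_tol,
                                      tuple(self.group_sizes))
        self.selected_features_ = feat
        self.selected_groups_ = grp
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        Xc, Z, _ = _design_parts(X, self.group_sizes)
        pred = self.intercept_ + Z @ self.coef_
        if self._q_:
            pred = pred + Xc @ self.beta_
        return pred

    def predict_h(self, X):
        """Feature-block part of the prediction (linear analogue of h)."""
        check_is_fitted(self, "coef_")
        _, Z, _ = _design_parts(X, self.group_sizes)
        return Z @ self.coef_
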