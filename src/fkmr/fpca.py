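"""Dense-design functional principal component analysis.

Curves observed on a common dense grid are decomposed by eigendecomposition
of the sample covariance operator under trapezoid quadrature.  Scores are
standardized by the square root of the eigenvalues and probit-transformed,
zeta_hat = Phi(xi_hat), so every retained feature lives on (0, 1) and is
approximately Uniform(0, 1) when the underlying scores are Gaussian.  These
zeta features are the inputs to the kernel machine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["FPCA", "FeatureBlocks", "fit_fpca", "project_scores", "build_feature_blocks"]

EIGENVALUE_FLOOR = 1e-12


class FPCA(BaseEstimator, TransformerMixin):
    """Functional PCA transformer for densely observed curves.

    Parameters
    ----------
    n_components : int, optional
        Number of leading components to retain.  If None, the smallest
        number reaching ``fve_threshold`` is used.
    fve_threshold : float, default 0.995
        Cumulative fraction-of-variance-explained cutoff used when
        ``n_components`` is None.
    grid : array-like of shape (m,), optional
        Sampling grid on [0, 1]; defaults to a uniform grid at fit time.

    Attributes
    ----------
    mean_curve_ : ndarray of shape (m,)
        Pointwise mean curve.
    eigenvalues_ : ndarray of shape (n_components,)
        Covariance-operator eigenvalues (variance scale), descending.
    eigenfunctions_ : ndarray of shape (n_components, m)
        Orthonormal (under quadrature) eigenfunctions; each is sign-fixed so
        its integral is positive (largest-magnitude value positive on ties).
    scores_std_ : ndarray of shape (n, n_components)
        Standardized training scores xi_hat (mean ~ 0, variance ~ 1).
    features_ : ndarray of shape (n, n_components)
        Probit-transformed training features zeta_hat = Phi(xi_hat).
    fve_ : ndarray
        Cumulative fraction of variance explained, over the full spectrum.
    """

    def __init__(self, n_components: int | None = None, fve_threshold: float = 0.995,
                 grid: np.ndarray | None = None):
        self.n_components = n_components
        self.fve_threshold = fve_threshold
        self.grid = grid

    def fit(self, X: np.ndarray, y: np.ndarray | None = None) -> "FPCA":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("X must be an (n >= 2) x m curve matrix")
        n, m = X.shape
        grid = (np.linspace(0.0, 1.0, m) if self.grid is None
                else np.asarray(self.grid, dtype=float))
        # Non-decreasing is enough: clipped jittered grids may carry boundary
        # ties, which get zero trapezoid weight.
        if grid.shape != (m,) or np.any(np.diff(grid) < 0) or grid[0] == grid[-1]:
            raise ValueError("grid must be sorted with at least two distinct points")

        w = _trapezoid_weights(grid)
        mean = X.mean(axis=0)
        centered = X - mean
        cov = centered.T @ centered / (n - 1)

        # Quadrature-weighted operator eigenproblem: W^1/2 C W^1/2.
        sqw = np.sqrt(w)
        sym = sqw[:, None] * cov * sqw[None, :]
        evals, evecs = np.linalg.eigh(sym)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0.0, None)
        # Zero-weight coordinates (duplicate grid points) carry no quadrature
        # mass; their eigenfunction values are set to zero.
        inv_sqw = np.divide(1.0, sqw, out=np.zeros_like(sqw), where=sqw > 0)
        phis = (evecs[:, order] * inv_sqw[:, None]).T  # rows orthonormal under w
        # A zero-weight coordinate is a duplicated grid point: give it the
        # value of its weighted twin so reconstructions stay exact.
        for i in np.flatnonzero(w == 0):
            twin = np.flatnonzero((grid == grid[i]) & (w > 0))
            if twin.size:
                phis[:, i] = phis[:, twin[0]]

        total = evals.sum()
        if total <= 0 or evals[0] <= 0:
            raise ValueError("degenerate curves: leading eigenvalue is not positive")
        fve = np.cumsum(evals) / total

        if self.n_components is not None:
            k = int(self.n_components)
            rank = int(np.sum(evals > max(EIGENVALUE_FLOOR, 1e-10 * evals[0])))
            if k > rank:
                raise ValueError(f"n_components={k} exceeds numerical rank {rank}")
        else:
            k = int(np.searchsorted(fve, self.fve_threshold) + 1)
            k = min(k, m)

        lam = evals[:k]
        phi = phis[:k]
        # Sign convention: positive quadrature integral, tie-broken by the
        # largest-magnitude value, so the fit is deterministic.
        for j in range(k):
            integral = float(phi[j] @ w)
            if abs(integral) > 1e-8:
                sign = np.sign(integral)
            else:
                sign = np.sign(phi[j][np.argmax(np.abs(phi[j]))])
            phi[j] *= sign if sign != 0 else 1.0

        self.grid_ = grid
        self.quad_weights_ = w
        self.mean_curve_ = mean
        self.eigenvalues_ = lam
        self.eigenfunctions_ = phi
        self.fve_ = fve
        self.n_components_ = k
        self.scores_std_ = self._scores(X)
        self.features_ = norm.cdf(self.scores_std_)
        return self

    def _scores(self, X: np.ndarray) -> np.ndarray:
        centered = np.asarray(X, dtype=float) - self.mean_curve_
        proj = centered @ (self.quad_weights_[:, None] * self.eigenfunctions_.T)
        return proj / np.sqrt(np.maximum(self.eigenvalues_, EIGENVALUE_FLOOR))

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project new curves on the training eigenfunctions; returns zeta."""
        check_is_fitted(self, "eigenfunctions_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.mean_curve_.shape[0]:
            raise ValueError("new curves must share the training grid")
        return norm.cdf(self._scores(X))

    def reconstruct(self, scores_std: np.ndarray) -> np.ndarray:
        """Rebuild centered curves from standardized scores (truncated KL sum)."""
        check_is_fitted(self, "eigenfunctions_")
        amp = scores_std * np.sqrt(np.maximum(self.eigenvalues_, EIGENVALUE_FLOOR))
        return amp @ self.eigenfunctions_


@dataclass
class FeatureBlocks:
    """Grand n x s feature matrix with contiguous per-functional groups."""

    matrix: np.ndarray
    group_sizes: tuple[int, ...]
    group_labels: tuple[str, ...]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_groups(self) -> int:
        return len(self.group_sizes)

    def group_slices(self) -> list[slice]:
        edges = np.concatenate([[0], np.cumsum(self.group_sizes)])
        return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


def _trapezoid_weights(grid: np.ndarray) -> np.ndarray:
    w = np.zeros_like(grid)
    d = np.diff(grid)
    w[:-1] += d / 2
    w[1:] += d / 2
    return w


def fit_fpca(curves: np.ndarray, grid: np.ndarray,
             n_components: int | None = None,
             fve_threshold: float = 0.995) -> FPCA:
    """Fit dense-design FPCA; thin wrapper over the :class:`FPCA` estimator."""
    return FPCA(n_components=n_components, fve_threshold=fve_threshold,
                grid=grid).fit(np.asarray(curves, dtype=float))


def project_scores(fpca: FPCA, new_curves: np.ndarray,
                   grid: np.ndarray | None = None) -> np.ndarray:
    """Probit features zeta for new subjects using the training fit only."""
    if grid is not None:
        grid = np.asarray(grid, dtype=float)
        if grid.shape != fpca.grid_.shape or not np.allclose(grid, fpca.grid_):
            raise ValueError("projection grid differs from the training grid")
    return fpca.transform(new_curves)


def build_feature_blocks(per_functional_features: list[np.ndarray],
                         labels: list[str] | None = None) -> FeatureBlocks:
    """Column-concatenate per-functional feature matrices into one block matrix."""
    if not per_functional_features:
        raise ValueError("need at least one feature block")
    mats = [np.atleast_2d(np.asarray(m, dtype=float)) for m in per_functional_features]
    n = mats[0].shape[0]
    if any(m.shape[0] != n for m in mats):
        raise ValueError("feature blocks have mismatched row counts")
    if labels is None:
        labels = [f"Z{i + 1}" for i in range(len(mats))]
    return FeatureBlocks(
        matrix=np.hstack(mats),
        group_sizes=tuple(m.shape[1] for m in mats),
        group_labels=tuple(labels),
    )
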