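"""Sparse and sparse-group penalties with a proximal path solver.

The penalized least-squares problem solved here,

    min_b (1/2n) ||y - D b||^2 + lambda * rho(b),

is the workhorse behind both the linearized garrote update and the linear
baselines.  Supported penalty families: lasso, group lasso, sparse group
lasso (SGL), MCP, and group MCP (MCP applied to the group norms).  The SGL
penalty uses the convention

    rho(b; delta) = (1 - delta) sum_l ||b_l||_2 + delta ||b||_1,

so delta = 0 recovers the group lasso and delta = 1 the lasso.  Convex
families are solved by FISTA with restart; the concave MCP families use
plain proximal gradient iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PenaltySpec", "penalty_value", "prox", "solve_penalized_ls",
           "lambda_max", "make_lambda_path", "cv_lambda"]

FAMILIES = ("lasso", "group_lasso", "sgl", "mcp", "group_mcp")
CONVEX = ("lasso", "group_lasso", "sgl")


@dataclass(frozen=True)
class PenaltySpec:
    """A penalty family with its mixing/concavity parameters and grouping.

    ``groups`` lists contiguous block sizes; it is required for the group
    families and for SGL.  ``delta`` is the SGL mixing weight on the l1 part.
    """

    family: str = "sgl"
    delta: float = 0.05
    mcp_a: float = 3.0
    groups: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown penalty family {self.family!r}")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must lie in [0, 1]")
        if self.mcp_a <= 1.0:
            raise ValueError("MCP concavity parameter must exceed 1")
        if self.family in ("group_lasso", "sgl", "group_mcp") and not self.groups:
            raise ValueError(f"{self.family} requires group sizes")

    @property
    def is_convex(self) -> bool:
        return self.family in CONVEX

    def group_slices(self, s: int) -> list[slice]:
        if not self.groups:
            return [slice(j, j + 1) for j in range(s)]
        if sum(self.groups) != s:
            raise ValueError("group sizes do not cover the coefficient vector")
        edges = np.concatenate([[0], np.cumsum(self.groups)])
        return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


def _mcp_value(t: np.ndarray, lam: float, a: float) -> np.ndarray:
    t = np.abs(t)
    inner = lam * t - t**2 / (2 * a)
    return np.where(t <= a * lam, inner, a * lam**2 / 2)


def penalty_value(v: np.ndarray, spec: PenaltySpec, lam: float = 1.0) -> float:
    """Evaluate lam * rho(v) for the spec's family."""
    v = np.asarray(v, dtype=float)
    sl = spec.group_slices(v.shape[0])
    gnorms = np.array([np.linalg.norm(v[s]) for s in sl])
    if spec.family == "lasso":
        return lam * float(np.abs(v).sum())
    if spec.family == "group_lasso":
        return lam * float(gnorms.sum())
    if spec.family == "sgl":
        return float(lam * ((1 - spec.delta) * gnorms.sum()
                            + spec.delta * np.abs(v).sum()))
    if spec.family == "mcp":
        return float(_mcp_value(v, lam, spec.mcp_a).sum())
    # group MCP: MCP function applied to each group norm
    return float(_mcp_value(gnorms, lam, spec.mcp_a).sum())


def _soft(v: np.ndarray, t: float) -> np.ndarray:
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)


def _group_shrink(v: np.ndarray, t: float, slices: list[slice]) -> np.ndarray:
    out = v.copy()
    for s in slices:
        nrm = np.linalg.norm(v[s])
        out[s] = 0.0 if nrm <= t else (1.0 - t / nrm) * v[s]
    return out


def _firm(v: np.ndarray, lam: float, step: float, a: float) -> np.ndarray:
    """Proximal operator of step * MCP(.; lam, a) (firm thresholding)."""
    if step >= a:  # concave part dominates the quadratic; fall back to soft
        return _soft(v, lam * step)
    out = _soft(v, lam * step) / (1.0 - step / a)
    return np.where(np.abs(v) > a * lam, v, out)


def prox(v: np.ndarray, threshold: float, spec: PenaltySpec,
         step: float | None = None) -> np.ndarray:
    """Proximal operator of threshold * rho at step size ``step``.

    ``threshold`` is lambda * step.  For the MCP families the step size
    itself matters and defaults to ``threshold`` (unit lambda).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    v = np.asarray(v, dtype=float)
    sl = spec.group_slices(v.shape[0])
    if spec.family == "lasso":
        return _soft(v, threshold)
    if spec.family == "group_lasso":
        return _group_shrink(v, threshold, sl)
    if spec.family == "sgl":
        return _group_shrink(_soft(v, spec.delta * threshold),
                             (1 - spec.delta) * threshold, sl)
    step = threshold if step is None else step
    lam = threshold / step
    if spec.family == "mcp":
        return _firm(v, lam, step, spec.mcp_a)
    out = v.copy()
    for s in sl:
        nrm = np.linalg.norm(v[s])
        if nrm == 0:
            continue
        shr = float(_firm(np.array([nrm]), lam, step, spec.mcp_a)[0])
        out[s] = (shr / nrm) * v[s]
    return out


def lambda_max(design: np.ndarray, response: np.ndarray, spec: PenaltySpec) -> float:
    """Smallest lambda for which b = 0 solves the penalized problem.

    For the MCP families the zero-solution threshold coincides with the
    corresponding (group-)lasso one, since MCP equals the l1 penalty near 0.
    """
    n = design.shape[0]
    g = design.T @ np.asarray(response, dtype=float) / n
    sl = spec.group_slices(g.shape[0])
    if spec.family in ("lasso", "mcp"):
        return float(np.max(np.abs(g))) if g.size else 0.0
    if spec.family in ("group_lasso", "group_mcp"):
        return float(max(np.linalg.norm(g[s]) for s in sl))
    # SGL: per group, smallest lam with ||soft(g_l, delta*lam)||_2 <= (1-delta)*lam
    delta = spec.delta
    if delta >= 1.0:
        return float(np.max(np.abs(g)))
    lams = []
    for s in sl:
        gl = g[s]
        hi = np.linalg.norm(gl) / (1 - delta)
        lo = 0.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if np.linalg.norm(_soft(gl, delta * mid)) <= (1 - delta) * mid:
                hi = mid
            else:
                lo = mid
        lams.append(hi)
    return float(max(lams))


def make_lambda_path(design: np.ndarray, response: np.ndarray, spec: PenaltySpec,
                     n_lambda: int = 100, ratio: float = 1e-3) -> np.ndarray:
    """Log-spaced decreasing path from lambda_max down to ratio * lambda_max."""
    lmax = lambda_max(design, response, spec)
    if lmax <= 0:
        lmax = 1.0
    return np.geomspace(lmax, ratio * lmax, n_lambda)


def _objective(design, response, b, b_free, unpen, lam, spec, n):
    r = response - design @ b
    if unpen is not None:
        r = r - unpen @ b_free
    return 0.5 * float(r @ r) / n + penalty_value(b, spec, lam)


def solve_penalized_ls(design: np.ndarray, response: np.ndarray, spec: PenaltySpec,
                       lambda_path: np.ndarray | float,
                       scale_n: int | None = None,
                       unpenalized: np.ndarray | None = None,
                       x0: np.ndarray | None = None,
                       max_iter: int = 2000, tol: float = 1e-9):
    """Proximal-gradient (FISTA) solution path of the penalized LS problem.

    Parameters
    ----------
    design, response : the n x s design and n-vector response.
    spec : penalty family, mixing and grouping.
    lambda_path : decreasing penalty levels (or a single scalar).
    scale_n : divisor of the quadratic loss (defaults to n).
    unpenalized : optional n x q block whose coefficients carry no penalty.
    x0 : warm start for the penalized coefficients.

    Returns
    -------
    coefs : (s, len(path)) penalized coefficients (or (s,) for scalar input).
    free_coefs : matching unpenalized coefficients, or None.
    converged : boolean flags per lambda.
    """
    design = np.asarray(design, dtype=float)
    response = np.asarray(response, dtype=float)
    n, s = design.shape
    n_eff = n if scale_n is None else int(scale_n)
    scalar_input = np.isscalar(lambda_path)
    path = np.atleast_1d(np.asarray(lambda_path, dtype=float))

    q = 0 if unpenalized is None else unpenalized.shape[1]
    full = design if q == 0 else np.hstack([unpenalized, design])
    L = (np.linalg.norm(full, 2) ** 2) / n_eff
    if L <= 0:
        zeros = np.zeros((s, path.size))
        free = None if q == 0 else np.zeros((q, path.size))
        out = (zeros[:, 0], None if free is None else free[:, 0], np.array([True])) \
            if scalar_input else (zeros, free, np.ones(path.size, bool))
        return out
    step = 1.0 / L

    b = np.zeros(s) if x0 is None else np.asarray(x0, dtype=float).copy()
    bf = np.zeros(q)
    coefs = np.zeros((s, path.size))
    frees = np.zeros((q, path.size))
    flags = np.zeros(path.size, dtype=bool)

    for k, lam in enumerate(path):
        z, zf, t_acc = b.copy(), bf.copy(), 1.0
        use_fista = spec.is_convex
        obj_prev = _objective(design, response, b, bf, unpenalized, lam, spec, n_eff)
        converged = False
        for it in range(max_iter):
            r = design @ z - response
            if q:
                r = r + unpenalized @ zf
            g = design.T @ r / n_eff
            b_new = prox(z - step * g, lam * step, spec, step=step)
            if q:
                bf_new = zf - step * (unpenalized.T @ r / n_eff)
            else:
                bf_new = zf
            if use_fista:
                t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_acc**2))
                z = b_new + ((t_acc - 1.0) / t_new) * (b_new - b)
                zf = bf_new + ((t_acc - 1.0) / t_new) * (bf_new - bf)
                t_acc = t_new
            else:
                z, zf = b_new.copy(), bf_new.copy()
            delta = max(np.max(np.abs(b_new - b)), np.max(np.abs(bf_new - bf))
                        if q else 0.0)
            b, bf = b_new, bf_new
            if use_fista and it % 10 == 9:  # restart if the objective rose
                obj = _objective(design, response, b, bf, unpenalized, lam, spec, n_eff)
                if obj > obj_prev + 1e-12:
                    z, zf, t_acc = b.copy(), bf.copy(), 1.0
                obj_prev = min(obj, obj_prev)
            if delta < tol * (1.0 + np.max(np.abs(b), initial=0.0)):
                converged = True
                break
        coefs[:, k] = b
        frees[:, k] = bf
        flags[k] = converged

    free_out = None if q == 0 else frees
    if scalar_input:
        return coefs[:, 0], None if free_out is None else frees[:, 0], flags
    return coefs, free_out, flags


def cv_lambda(design: np.ndarray, response: np.ndarray, spec: PenaltySpec,
              folds: int = 5, lambda_path: np.ndarray | None = None,
              rng: np.random.Generator | int | None = None,
              unpenalized: np.ndarray | None = None,
              one_se: bool = False) -> tuple[float, np.ndarray]:
    """K-fold cross-validated penalty level (min-MSE rule by default).

    Returns the selected lambda and the mean CV error along the path.
    Fold assignment is a seeded permutation, so the result is deterministic
    given the rng state.
    """
    design = np.asarray(design, dtype=float)
    response = np.asarray(response, dtype=float)
    n = design.shape[0]
    if folds < 2:
        raise ValueError("need at least 2 folds")
    if n < folds:
        raise ValueError("more folds than observations")
    if lambda_path is None:
        lambda_path = make_lambda_path(design, response, spec)
    rng = np.random.default_rng(rng)
    perm = rng.permutation(n)
    fold_ids = np.array_split(perm, folds)

    errs = np.zeros((folds, lambda_path.size))
    for f, val in enumerate(fold_ids):
        mask = np.ones(n, dtype=bool)
        mask[val] = False
        unp_tr = None if unpenalized is None else unpenalized[mask]
        coefs, frees, _ = solve_penalized_ls(design[mask], response[mask], spec,
                                             lambda_path, unpenalized=unp_tr)
        pred = design[val] @ coefs
        if frees is not None:
            pred = pred + unpenalized[val] @ frees
        errs[f] = np.mean((response[val, None] - pred) ** 2, axis=0)

    mean_err = errs.mean(axis=0)
    best = int(np.argmin(mean_err))
    if one_se:
        se = errs.std(axis=0, ddof=1) / np.sqrt(folds)
        cutoff = mean_err[best] + se[best]
        best = int(np.argmax(mean_err <= cutoff))  # largest lambda within 1 SE
    return float(lambda_path[best]), mean_err
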