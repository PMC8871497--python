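"""Performance metrics and the replicate simulation study.

Accuracy is summarized on a held-out test set by the quasi-R2 and its
size-adjusted version, and the quality of the estimated surface h by a
concordance regression: OLS of the true (centered) h on the estimated h at
the test design points, where intercept 0 / slope 1 / R2 1 indicate perfect
functional recovery.  Selection stability across replicates is reported as
per-group and per-feature selection frequencies with sensitivity and
specificity against the generating truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .baselines import PenalizedLinearModel
from .fkmr import FKMRRegressor
from .fpca import build_feature_blocks, fit_fpca
from .kernels import KernelSpec, kernel_cross
from .lskm import predict_lskm, reml_fit
from .simulate import ScenarioConfig, simulate_dataset

__all__ = [
    "quasi_r2", "adjusted_quasi_r2", "concordance_regression",
    "marginal_curve", "selection_metrics", "replicate_study",
    "EvaluationReport", "ReplicateSummary", "KNOWN_METHODS",
]

FKMR_PENALTIES = ("lasso", "glasso", "sgl", "mcp", "gmcp")
KNOWN_METHODS = tuple(
    [f"fkmr:{p}" for p in FKMR_PENALTIES]
    + ["fkmr_oracle_features", "fkmr_oracle_signals"]
    + [f"lm:{p}" for p in FKMR_PENALTIES]
)


def quasi_r2(y: np.ndarray, yhat: np.ndarray) -> float:
    """1 - SSE/SST on held-out data, SST about the held-out mean."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have equal length")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst <= 0:
        raise ValueError("quasi-R2 undefined for constant y")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / sst


def adjusted_quasi_r2(rq2: float, n: int, k: int) -> float:
    """Size-adjusted quasi-R2: 1 - (1 - RQ2)(n - 1)/(n - (k + 1))."""
    if n <= k + 1:
        raise ValueError("need n > k + 1 for the adjustment")
    return 1.0 - (1.0 - rq2) * (n - 1) / (n - (k + 1))


def concordance_regression(h_true: np.ndarray,
                           h_hat: np.ndarray) -> tuple[float, float, float]:
    """OLS of the true h on the estimated h: (intercept, slope, R2)."""
    h_true = np.asarray(h_true, dtype=float)
    h_hat = np.asarray(h_hat, dtype=float)
    if np.std(h_hat) == 0:
        raise ValueError("concordance regression undefined for constant h_hat")
    res = linregress(h_hat, h_true)
    return float(res.intercept), float(res.slope), float(res.rvalue**2)


def marginal_curve(fit, feature_index: int, n_grid: int = 100,
                   baseline: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Estimated h along one feature with all others pinned at ``baseline``.

    Evaluates the kernel part of a fitted :class:`FKMRRegressor` on synthetic
    feature vectors whose ``feature_index`` coordinate sweeps a uniform grid
    on [0, 1]; the scalar-covariate contribution is excluded.
    """
    s = fit.Z_train_.shape[1]
    if not 0 <= feature_index < s:
        raise IndexError(f"feature index {feature_index} out of range for s={s}")
    grid = np.linspace(0.0, 1.0, n_grid)
    pts = np.full((n_grid, s), baseline)
    pts[:, feature_index] = grid
    kspec = KernelSpec(bandwidth_denominator=float(s))
    values = kernel_cross(pts, fit.Z_train_, fit.gamma_, kspec) @ fit.alpha_
    return grid, values


def plot_marginal_curves(fit, feature_indices, labels=None, ax=None):
    """Plot estimated marginal effect curves (requires matplotlib)."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    for i, j in enumerate(feature_indices):
        grid, vals = marginal_curve(fit, j)
        label = labels[i] if labels else f"feature {j}"
        ax.plot(grid, vals, label=label)
    ax.set_xlabel("feature value")
    ax.set_ylabel("estimated h (others at 0.5)")
    ax.legend()
    return ax


def selection_metrics(selected: np.ndarray, truth_indices) -> dict:
    """Selection frequencies (%) with sensitivity and specificity.

    ``selected`` is a replicates x items boolean array; ``truth_indices``
    are the item indices that are truly in the model.
    """
    selected = np.atleast_2d(np.asarray(selected, dtype=bool))
    n_items = selected.shape[1]
    truth = np.zeros(n_items, dtype=bool)
    truth[np.asarray(list(truth_indices), dtype=int)] = True
    freq = 100.0 * selected.mean(axis=0)
    sens = float(freq[truth].mean()) if truth.any() else np.nan
    spec = float((100.0 - freq[~truth]).mean()) if (~truth).any() else np.nan
    return {"frequency": freq, "sensitivity": sens, "specificity": spec}


@dataclass
class EvaluationReport:
    """Test-set metrics for one fitted method on one replicate."""

    rq2: float
    raq2: float
    concordance_intercept: float
    concordance_slope: float
    concordance_r2: float
    beta_hat: np.ndarray
    group_selected: np.ndarray
    feature_selected: np.ndarray
    k: int


@dataclass
class ReplicateSummary:
    """Aggregated replicate-study results (Table 1-4 analogues)."""

    scenario: int
    methods: tuple[str, ...]
    n_replicates: int
    n_subjects: int
    seeds: tuple[int, ...]
    metrics: pd.DataFrame  # per-method means: raq2, rq2, beta, intercept, slope, r2
    group_frequency: pd.DataFrame  # % of replicates each group is selected
    feature_frequency: pd.DataFrame  # % of replicates each feature is selected
    selection: dict = field(default_factory=dict)  # per-method sens/spec
    failures: list = field(default_factory=list)
    records: pd.DataFrame | None = None


def _child_seed(master: int, replicate: int) -> int:
    return int((master * 100003 + replicate) % (2**31 - 1))


def _evaluate_fit(model, X_test, y_test, h_true_test, n_groups, s, q) -> EvaluationReport:
    yhat = model.predict(X_test)
    rq2 = quasi_r2(y_test, yhat)
    k = int(len(model.selected_features_)) + q
    raq2 = adjusted_quasi_r2(rq2, len(y_test), k)
    h_hat = model.predict_h(X_test)
    ic, sl, r2 = concordance_regression(h_true_test - h_true_test.mean(), h_hat)
    gsel = np.zeros(n_groups, dtype=bool)
    gsel[model.selected_groups_] = True
    fsel = np.zeros(s, dtype=bool)
    fsel[model.selected_features_] = True
    beta = getattr(model, "beta_", np.empty(0))
    return EvaluationReport(rq2=rq2, raq2=raq2, concordance_intercept=ic,
                            concordance_slope=sl, concordance_r2=r2,
                            beta_hat=np.atleast_1d(beta),
                            group_selected=gsel, feature_selected=fsel, k=k)


class _OracleSignalModel:
    """Unpenalized kernel machine on the true signal features only."""

    def __init__(self, signal_indices, n_groups, group_sizes):
        self.signal_indices = np.asarray(signal_indices, dtype=int)
        self.n_groups = n_groups
        self.group_sizes = group_sizes

    def fit(self, Xc, Z_signal, y):
        self._kspec = KernelSpec(bandwidth_denominator=float(Z_signal.shape[1]))
        from .kernels import kernel_matrix
        K = kernel_matrix(Z_signal, np.ones(Z_signal.shape[1]), self._kspec)
        self._fit = reml_fit(y, Xc, K)
        self._Ztr = Z_signal
        self.beta_ = self._fit.beta
        self.selected_features_ = self.signal_indices
        edges = np.concatenate([[0], np.cumsum(self.group_sizes)])
        self.selected_groups_ = np.unique(
            [int(np.searchsorted(edges, i, side="right") - 1)
             for i in self.signal_indices])
        return self

    def _cross(self, Z_signal):
        return kernel_cross(Z_signal, self._Ztr,
                            np.ones(self._Ztr.shape[1]), self._kspec)

    def predict(self, Xc, Z_signal):
        return predict_lskm(self._fit, Xc, self._cross(Z_signal))

    def predict_h(self, Z_signal):
        return self._cross(Z_signal) @ self._fit.alpha


def replicate_study(scenario: int, methods, n_replicates: int, n: int = 1000,
                    seed: int = 0, delta: float = 0.05,
                    keep_records: bool = True) -> ReplicateSummary:
    """Run the full simulate / FPCA / fit / evaluate loop over replicates.

    Every method within a replicate sees the identical dataset; replicate r
    uses generator seed ``seed + r`` and a method-internal CV seed derived
    from (seed, r).  Results are averaged into Table-style summaries.
    """
    methods = tuple(methods)
    unknown = [m for m in methods if m not in KNOWN_METHODS]
    if unknown:
        raise ValueError(f"unknown methods: {unknown}")

    rows, failures = [], []
    first_cfg = ScenarioConfig(scenario=scenario, n_subjects=n, seed=seed)
    p = first_cfg.n_functionals
    J = first_cfg.n_basis_per_functional
    s = p * J

    for r in range(n_replicates):
        cfg = ScenarioConfig(scenario=scenario, n_subjects=n, seed=seed + r)
        ds = simulate_dataset(cfg)
        tr, te = ds.train_index, ds.test_index
        fpcas = [fit_fpca(c[tr], ds.grid, n_components=J) for c in ds.curves]
        blocks_tr = build_feature_blocks([f.features_ for f in fpcas])
        blocks_te = build_feature_blocks(
            [f.transform(c[te]) for f, c in zip(fpcas, ds.curves)])
        Xc_tr, Xc_te = ds.x[tr][:, None], ds.x[te][:, None]
        X_tr = np.hstack([Xc_tr, blocks_tr.matrix])
        X_te = np.hstack([Xc_te, blocks_te.matrix])
        y_tr, y_te = ds.y[tr], ds.y[te]
        h_te = ds.true_h[te]
        rs = _child_seed(seed, r)

        for method in methods:
            try:
                rep = _fit_one(method, cfg, ds, X_tr, y_tr, X_te, y_te, h_te,
                               Xc_tr, Xc_te, delta, rs)
            except Exception as exc:  # recorded, not fatal
                failures.append({"replicate": r, "method": method,
                                 "error": repr(exc)})
                continue
            rows.append({"replicate": r, "method": method, "raq2": rep.raq2,
                         "rq2": rep.rq2, "beta": float(rep.beta_hat[0])
                         if rep.beta_hat.size else np.nan,
                         "intercept": rep.concordance_intercept,
                         "slope": rep.concordance_slope,
                         "r2": rep.concordance_r2, "k": rep.k,
                         "group_selected": rep.group_selected,
                         "feature_selected": rep.feature_selected})

    rec = pd.DataFrame(rows)
    metric_cols = ["raq2", "rq2", "beta", "intercept", "slope", "r2", "k"]
    metrics = rec.groupby("method", sort=False)[metric_cols].mean() \
        .reindex(list(methods))
    gfreq = pd.DataFrame(
        {m: 100.0 * np.mean(np.stack(rec.loc[rec.method == m,
                                             "group_selected"]), axis=0)
         for m in methods if (rec.method == m).any()},
        index=[f"Z{g + 1}" for g in range(p)]).T
    ffreq = pd.DataFrame(
        {m: 100.0 * np.mean(np.stack(rec.loc[rec.method == m,
                                             "feature_selected"]), axis=0)
         for m in methods if (rec.method == m).any()},
        index=[f"zeta{j + 1}{g + 1}" for g in range(p) for j in range(J)]).T

    selection = {}
    ds0 = simulate_dataset(ScenarioConfig(scenario=scenario, n_subjects=4,
                                          seed=seed))
    for m in methods:
        sub = rec.loc[rec.method == m]
        if not len(sub):
            continue
        selection[m] = {
            "groups": selection_metrics(np.stack(sub["group_selected"]),
                                        ds0.signal_group_indices),
            "features": selection_metrics(np.stack(sub["feature_selected"]),
                                          ds0.signal_feature_indices),
        }

    return ReplicateSummary(
        scenario=scenario, methods=methods, n_replicates=n_replicates,
        n_subjects=n, seeds=tuple(seed + r for r in range(n_replicates)),
        metrics=metrics, group_frequency=gfreq, feature_frequency=ffreq,
        selection=selection, failures=failures,
        records=rec if keep_records else None)


def _fit_one(method, cfg, ds, X_tr, y_tr, X_te, y_te, h_te, Xc_tr, Xc_te,
             delta, random_state) -> EvaluationReport:
    group_sizes = cfg.group_sizes
    p, s, q = cfg.n_functionals, sum(group_sizes), Xc_tr.shape[1]
    tr, te = ds.train_index, ds.test_index

    if method == "fkmr_oracle_signals":
        idx = ds.signal_feature_indices
        om = _OracleSignalModel(idx, p, group_sizes)
        om.fit(Xc_tr, ds.true_zeta[tr][:, idx], y_tr)
        yhat = om.predict(Xc_te, ds.true_zeta[te][:, idx])
        rq2 = quasi_r2(y_te, yhat)
        k = len(idx) + q
        raq2 = adjusted_quasi_r2(rq2, len(y_te), k)
        ic, sl, r2 = concordance_regression(
            h_te - h_te.mean(), om.predict_h(ds.true_zeta[te][:, idx]))
        gsel = np.zeros(p, dtype=bool)
        gsel[om.selected_groups_] = True
        fsel = np.zeros(s, dtype=bool)
        fsel[idx] = True
        return EvaluationReport(rq2, raq2, ic, sl, r2, np.atleast_1d(om.beta_),
                                gsel, fsel, k)

    if method == "fkmr_oracle_features":
        model = FKMRRegressor(group_sizes=group_sizes, penalty="gmcp",
                              delta=delta, random_state=random_state)
        Xo_tr = np.hstack([Xc_tr, ds.true_zeta[tr]])
        Xo_te = np.hstack([Xc_te, ds.true_zeta[te]])
        model.fit(Xo_tr, y_tr)
        return _evaluate_fit(model, Xo_te, y_te, h_te, p, s, q)

    kind, _, pen = method.partition(":")
    if kind == "fkmr":
        model = FKMRRegressor(group_sizes=group_sizes, penalty=pen,
                              delta=delta, random_state=random_state)
    else:
        model = PenalizedLinearModel(group_sizes=group_sizes, penalty=pen,
                                     delta=delta, random_state=random_state)
    model.fit(X_tr, y_tr)
    return _evaluate_fit(model, X_te, y_te, h_te, p, s, q)
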