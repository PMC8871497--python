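import numpy as np
import pytest

from fkmr.fkmr import (FKMRRegressor, linearize, objective_J2, selected_features,
                       update_gamma)
from fkmr.kernels import KernelSpec, kernel_matrix
from fkmr.lskm import reml_fit
from fkmr.penalties import PenaltySpec, lambda_max, penalty_value


@pytest.fixture(scope="module")
def toy_state(scenario2_features_small):
    """A small kernel-machine state (beta, alpha, lambda1) at gamma = 1."""
    Z, x, y = scenario2_features_small
    kspec = KernelSpec(float(Z.shape[1]))
    K = kernel_matrix(Z, np.ones(Z.shape[1]), kspec)
    fit = reml_fit(y, x[:, None], K)
    return Z, x[:, None], y, fit, kspec, K


@pytest.fixture(scope="module")
def scenario2_features_small():
    from fkmr.simulate import ScenarioConfig, simulate_dataset
    ds = simulate_dataset(ScenarioConfig(scenario=2, n_subjects=120, seed=17))
    return ds.true_zeta, ds.x, ds.y


class TestObjective:
    def test_zero_coefficients(self):
        y = np.array([1.0, 2.0, 3.0])
        Z = np.random.default_rng(0).uniform(size=(3, 2))
        spec = PenaltySpec("lasso")
        kspec = KernelSpec(2.0)
        gamma = np.array([0.5, 1.0])
        val = objective_J2(y, None, Z, None, np.zeros(3), gamma, 1.0, 2.0,
                          spec, kspec)
        expected = (y @ y) / 6 + 2.0 * penalty_value(gamma, spec)
        assert val == pytest.approx(expected)

    def test_lemma2_constant_offset(self, toy_state):
        """Eq.-(6) objective minus its gamma-subproblem form is constant in
        gamma (the Lemma-2 equivalence)."""
        Z, X, y, fit, kspec, _ = toy_state
        n = len(y)
        spec = PenaltySpec("sgl", 0.05, groups=(9, 9, 9, 9))
        lam1, lam2 = fit.lambda1, 0.7
        ytil = y - X @ fit.beta - 0.5 * n * lam1 * fit.alpha
        rng = np.random.default_rng(1)
        offsets = []
        for _ in range(50):
            gamma = rng.normal(size=36)
            K = kernel_matrix(Z, gamma, kspec)
            j2 = objective_J2(y, X, Z, fit.beta, fit.alpha, gamma, lam1, lam2,
                             spec, kspec, K=K)
            r = K @ fit.alpha - ytil
            sub = 0.5 * (r @ r) / n + penalty_value(gamma, spec, lam2)
            offsets.append(j2 - sub)
        offsets = np.asarray(offsets)
        scale = max(abs(offsets.mean()), 1.0)
        assert offsets.std() < 1e-9 * scale


class TestLinearize:
    def test_zero_alpha_degenerate(self, toy_state):
        Z, X, y, fit, kspec, _ = toy_state
        design, response = linearize(y, X, Z, fit.beta, np.zeros(len(y)),
                                     np.ones(36), fit.lambda1, kspec)
        assert np.allclose(design, 0.0)
        assert np.allclose(response, y - X @ fit.beta)

    def test_shapes(self, toy_state):
        Z, X, y, fit, kspec, K = toy_state
        design, response = linearize(y, X, Z, fit.beta, fit.alpha,
                                     np.ones(36), fit.lambda1, kspec, K=K)
        assert design.shape == Z.shape and response.shape == y.shape

    def test_first_order_taylor_accuracy(self, toy_state):
        """Halving the perturbation divides the linearization error ~4x."""
        Z, X, y, fit, kspec, K = toy_state
        gamma = np.ones(36)
        design, _ = linearize(y, X, Z, fit.beta, fit.alpha, gamma,
                              fit.lambda1, kspec, K=K)
        F0 = K @ fit.alpha
        rng = np.random.default_rng(4)
        direction = rng.normal(size=36)
        errs = []
        for eps in (0.1, 0.05, 0.025):
            g = gamma + eps * direction
            F = kernel_matrix(Z, g, kspec) @ fit.alpha
            lin = F0 + design @ (g - gamma)
            errs.append(np.linalg.norm(F - lin))
        assert errs[1] < errs[0] / 2.5
        assert errs[2] < errs[1] / 2.5

    def test_nonfinite_alpha_rejected(self, toy_state):
        Z, X, y, fit, kspec, _ = toy_state
        bad = fit.alpha.copy()
        bad[0] = np.nan
        with pytest.raises(ValueError):
            linearize(y, X, Z, fit.beta, bad, np.ones(36), fit.lambda1, kspec)


class TestUpdateGamma:
    def test_huge_lambda2_zeroes_gamma(self, toy_state):
        Z, X, y, fit, kspec, K = toy_state
        spec = PenaltySpec("sgl", 0.05, groups=(9, 9, 9, 9))
        design, response = linearize(y, X, Z, fit.beta, fit.alpha, np.ones(36),
                                     fit.lambda1, kspec, K=K)
        lam = 10 * lambda_max(design, response, spec)
        gamma, trace, stalled, _, _ = update_gamma(
            y, X, Z, fit.beta, fit.alpha, np.ones(36), fit.lambda1, lam,
            spec, kspec, K0=K)
        assert np.allclose(gamma, 0.0)

    def test_descent_of_subproblem_objective(self, toy_state):
        Z, X, y, fit, kspec, K = toy_state
        spec = PenaltySpec("sgl", 0.05, groups=(9, 9, 9, 9))
        _, trace, _, _, _ = update_gamma(y, X, Z, fit.beta, fit.alpha,
                                         np.ones(36), fit.lambda1, 0.5,
                                         spec, kspec, K0=K)
        diffs = np.diff(np.asarray(trace))
        assert np.all(diffs <= 1e-8 * (1 + np.abs(trace[:-1])))

    def test_matches_grid_search_single_feature(self):
        """lambda2 = 0, s = 1: the update lands on the 1-D minimizer."""
        rng = np.random.default_rng(6)
        n = 20
        Z = rng.uniform(size=(n, 1))
        alpha = rng.normal(size=n) * 0.5
        y = rng.normal(size=n)
        kspec = KernelSpec(1.0)
        spec = PenaltySpec("lasso")
        lam1 = 0.01
        ytil = y - 0.5 * n * lam1 * alpha

        def loss(g):
            r = kernel_matrix(Z, np.array([g]), kspec) @ alpha - ytil
            return 0.5 * (r @ r) / n

        grid = np.linspace(0.01, 5, 1200)
        g_best = grid[np.argmin([loss(g) for g in grid])]
        gamma, _, _, _, _ = update_gamma(y, None, Z, None, alpha,
                                         np.ones(1), lam1, 1e-12, spec, kspec)
        assert loss(abs(gamma[0])) <= loss(1.0) + 1e-12
        assert abs(abs(gamma[0]) - g_best) < 0.05


class TestSelectedFeatures:
    def test_zero_gamma(self):
        feat, grp = selected_features(np.zeros(6), 1e-6, (3, 3))
        assert feat.size == 0 and grp.size == 0

    def test_last_feature_only(self):
        feat, grp = selected_features(np.array([0, 0, 0, 0, 0, 1.0]), 1e-6,
                                      (3, 3))
        assert list(feat) == [5] and list(grp) == [1]

    def test_tolerance_monotonicity(self):
        rng = np.random.default_rng(0)
        gamma = rng.normal(size=8) * [1, 0.1, 0.01, 0, 1, 0.5, 0.001, 2]
        prev_f = prev_g = 9
        for tol in (1e-6, 1e-3, 0.05, 0.5):
            feat, grp = selected_features(gamma, tol, (4, 4))
            assert len(feat) <= prev_f and len(grp) <= prev_g
            prev_f, prev_g = len(feat), len(grp)


class TestFKMRRegressor:
    @pytest.fixture(scope="class")
    def fitted(self, scenario2_small):
        d = scenario2_small
        model = FKMRRegressor(group_sizes=(9, 9, 9, 9), penalty="sgl",
                              delta=0.05, random_state=0)
        return model.fit(d["X_train"], d["y_train"]), d

    def test_selects_signal_groups(self, fitted):
        model, _ = fitted
        assert set(model.selected_groups_) <= {0, 1}
        assert {0, 1} & set(model.selected_groups_)

    def test_objective_trace_nonincreasing(self, fitted):
        model, _ = fitted
        tr = model.objective_trace_
        assert np.all(np.diff(tr) <= 1e-8 * (1 + np.abs(tr[:-1])))

    def test_training_prediction_consistency(self, fitted):
        from fkmr.kernels import kernel_cross
        model, d = fitted
        pred = model.predict(d["X_train"])
        manual = d["X_train"][:, :1] @ model.beta_ + kernel_cross(
            d["X_train"][:, 1:], model.Z_train_, model.gamma_,
            model._kspec_) @ model.alpha_
        assert np.allclose(pred, manual)

    def test_sign_invariance_of_predictions(self, fitted):
        model, d = fitted
        flipped = model.gamma_.copy()
        flipped[::2] *= -1
        base = model.predict(d["X_test"])
        orig = model.gamma_
        try:
            model.gamma_ = flipped
            assert np.allclose(model.predict(d["X_test"]), base)
        finally:
            model.gamma_ = orig

    def test_beta_near_truth(self, fitted):
        model, _ = fitted
        assert model.beta_[0] == pytest.approx(2.0, abs=0.4)

    def test_gamma_reported_nonnegative(self, fitted):
        model, _ = fitted
        assert np.all(model.gamma_ >= 0)

    def test_sklearn_get_set_params_roundtrip(self):
        model = FKMRRegressor(group_sizes=(9, 9), penalty="glasso")
        clone = FKMRRegressor(**model.get_params())
        assert clone.get_params() == model.get_params()

    def test_pure_noise_selects_nothing(self):
        from fkmr.simulate import ScenarioConfig, simulate_dataset
        from fkmr.fpca import fit_fpca
        empty = 0
        for s in range(10):
            ds = simulate_dataset(ScenarioConfig(scenario=2, n_subjects=300,
                                                 seed=200 + s))
            tr = ds.train_index
            Z = np.hstack([fit_fpca(c[tr], ds.grid, 9).features_
                           for c in ds.curves])
            y_noise = np.random.default_rng(900 + s).standard_normal(len(tr))
            m = FKMRRegressor(group_sizes=(9, 9, 9, 9), penalty="sgl",
                              random_state=s)
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m.fit(np.hstack([ds.x[tr][:, None], Z]), y_noise)
            empty += len(m.selected_groups_) == 0
        assert empty >= 8

    def test_fixed_lambda2_skips_selection_of_lambda(self, scenario2_small):
        d = scenario2_small
        m = FKMRRegressor(group_sizes=(9, 9, 9, 9), penalty="sgl",
                          lambda2=5.0, random_state=1)
        m.fit(d["X_train"], d["y_train"])
        assert m.lambda2_ == 5.0

    def test_unknown_penalty_rejected(self, scenario2_small):
        d = scenario2_small
        with pytest.raises(ValueError):
            FKMRRegressor(group_sizes=(9, 9, 9, 9),
                          penalty="ridge").fit(d["X_train"], d["y_train"])


class TestAlgorithm1:
    def test_agrees_with_algorithm2_on_signal_groups(self, scenario2_small):
        d = scenario2_small
        m2 = FKMRRegressor(group_sizes=(9, 9, 9, 9), penalty="sgl",
                           algorithm=2, random_state=3)
        m2.fit(d["X_train"], d["y_train"])
        m1 = FKMRRegressor(group_sizes=(9, 9, 9, 9), penalty="sgl",
                           algorithm=1, lambda1_grid=[1e-4],
                           lambda2_grid=[3.0, 30.0], cv=3, random_state=3)
        m1.fit(d["X_train"], d["y_train"])
        assert set(m1.selected_groups_) == set(m2.selected_groups_)
        assert np.all(np.diff(m1.objective_trace_)
                      <= 1e-8 * (1 + np.abs(m1.objective_trace_[:-1])))

    def test_single_pair_reduces_to_alternation(self, scenario2_small):
        d = scenario2_small
        m = FKMRRegressor(group_sizes=(9, 9, 9, 9), penalty="sgl",
                          algorithm=1, lambda1_grid=[1e-3],
                          lambda2_grid=[5.0], random_state=4)
        m.fit(d["X_train"], d["y_train"])
        assert m.lambda1_ == 1e-3 and m.lambda2_ == 5.0
        assert m.n_outer_iterations_ >= 1

    def test_empty_grid_rejected(self, scenario2_small):
        d = scenario2_small
        with pytest.raises(ValueError):
            FKMRRegressor(group_sizes=(9, 9, 9, 9), algorithm=1,
                          lambda1_grid=[], lambda2_grid=[1.0]).fit(
                              d["X_train"], d["y_train"])
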