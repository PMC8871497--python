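import numpy as np
import pytest

from fkmr.kernels import KernelSpec, kernel_matrix
from fkmr.lskm import (DegenerateKernelWarning, predict_lskm, reml_fit,
                       solve_fixed_lambda)


@pytest.fixture(scope="module")
def kernel_750(scenario2_features_750):
    Z, _ = scenario2_features_750
    return kernel_matrix(Z, np.ones(Z.shape[1]), KernelSpec(Z.shape[1]))


@pytest.fixture(scope="module")
def scenario2_features_750():
    from fkmr.simulate import ScenarioConfig, simulate_dataset
    ds = simulate_dataset(ScenarioConfig(scenario=2, n_subjects=750, seed=21))
    return ds.true_zeta, ds


class TestClosedForm:
    def test_identity_kernel_example(self):
        # (K + n*lambda1*I) alpha = Y with K = I, n = 2, lambda1 = 0.5
        beta, alpha = solve_fixed_lambda(np.array([2.0, 4.0]), None,
                                         np.eye(2), 0.5)
        assert np.allclose(alpha, [1.0, 2.0], atol=1e-8)
        assert beta.size == 0

    def test_infinite_penalty_limit(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 2))
        y = X @ [1.0, -2.0] + rng.normal(size=40)
        K = kernel_matrix(rng.uniform(size=(40, 3)), np.ones(3), KernelSpec(3.0))
        beta, alpha = solve_fixed_lambda(y, X, K, 1e8)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(beta, ols, atol=1e-4)
        assert np.max(np.abs(K @ alpha)) < 1e-4

    def test_stationary_point_is_local_minimum(self):
        rng = np.random.default_rng(5)
        n = 25
        X = rng.normal(size=(n, 1))
        y = rng.normal(size=n)
        K = kernel_matrix(rng.uniform(size=(n, 3)), np.ones(3), KernelSpec(3.0))
        lam1 = 0.05
        beta, alpha = solve_fixed_lambda(y, X, K, lam1)

        def objective(b, a):
            r = y - X @ b - K @ a
            return 0.5 * r @ r / n + 0.5 * lam1 * a @ K @ a

        base = objective(beta, alpha)
        for _ in range(100):
            db = beta + 1e-3 * rng.normal(size=1)
            da = alpha + 1e-3 * rng.normal(size=n)
            assert objective(db, da) >= base - 1e-12

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            solve_fixed_lambda(np.ones(3), None, np.eye(3), -1.0)
        X = np.ones((4, 2))  # duplicated column -> rank deficient
        with pytest.raises(np.linalg.LinAlgError):
            solve_fixed_lambda(np.ones(4), X, np.eye(4), 0.1)


class TestReml:
    def test_parameter_recovery(self, scenario2_features_750):
        """Median relative error of (tau, sigma2) over simulated LMM fits.

        40 replicates keep the Monte-Carlo error of the median small; the
        kernel variance tau is weakly identified (its per-fit error
        distribution has median ~0.2), so a small replicate count would make
        this check a coin flip.
        """
        Z, ds = scenario2_features_750
        K = kernel_matrix(Z, np.ones(36), KernelSpec(36.0))
        n = 750
        d, U = np.linalg.eigh(K + 1e-10 * np.eye(n))
        d = np.clip(d, 0, None)
        tau, sigma2 = 2.0, 1.0
        root = U * np.sqrt(tau * d)
        errs = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(n, 1))
            h = root @ rng.standard_normal(n)
            y = X[:, 0] * 1.5 + h + rng.normal(0, np.sqrt(sigma2), n)
            fit = reml_fit(y, X, K, eig=(d, U))
            errs.append([abs(fit.tau - tau) / tau,
                         abs(fit.sigma2 - sigma2) / sigma2])
        med = np.median(np.asarray(errs), axis=0)
        assert med[0] < 0.25 and med[1] < 0.25

    def test_exact_linear_data_hits_boundary(self):
        X = np.linspace(0, 1, 30)[:, None]
        y = 3.0 * X[:, 0]
        K = kernel_matrix(np.random.default_rng(0).uniform(size=(30, 2)),
                          np.ones(2), KernelSpec(2.0))
        with pytest.warns(DegenerateKernelWarning):
            fit = reml_fit(y, X, K)
        assert fit.no_kernel_effect

    def test_identity_kernel_warns(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=30)
        with pytest.warns(DegenerateKernelWarning):
            reml_fit(y, None, np.eye(30))

    def test_route_equivalence(self, scenario2_features_750):
        """REML (beta, alpha) equals the closed form at lambda1 = s2/(n tau)."""
        Z, ds = scenario2_features_750
        K = kernel_matrix(Z, np.ones(36), KernelSpec(36.0))
        X = ds.x[:, None]
        fit = reml_fit(ds.y, X, K)
        beta, alpha = solve_fixed_lambda(ds.y, X, K, fit.lambda1)
        assert np.max(np.abs(beta - fit.beta)) < 1e-6
        assert np.max(np.abs(alpha - fit.alpha)) < 1e-6
        assert fit.lambda1 == pytest.approx(fit.sigma2 / (750 * fit.tau))
        assert np.max(np.abs(fit.h_hat - K @ fit.alpha)) < 1e-8

    def test_optimum_beats_theta_grid(self, scenario2_features_750):
        Z, ds = scenario2_features_750
        K = kernel_matrix(Z, np.ones(36), KernelSpec(36.0))
        X = ds.x[:, None]
        n, q = 750, 1
        fit = reml_fit(ds.y, X, K)
        d, U = np.linalg.eigh(K + 1e-10 * np.eye(n))
        yt, Xt = U.T @ ds.y, U.T @ X

        def crit(theta):
            w = theta * np.clip(d, 0, None) + 1.0
            Xw = Xt / w[:, None]
            A = Xt.T @ Xw
            beta = np.linalg.solve(A, Xw.T @ yt)
            r = yt - Xt @ beta
            s2 = (r @ (r / w)) / (n - q)
            return (n - q) * np.log(s2) + np.sum(np.log(w)) \
                + np.linalg.slogdet(A)[1]

        theta_hat = fit.tau / fit.sigma2
        best = crit(theta_hat)
        for theta in theta_hat * np.geomspace(0.2, 5.0, 20):
            assert crit(theta) >= best - 1e-6


class TestPredict:
    def test_training_prediction_reproduces_fit(self, scenario2_features_750):
        Z, ds = scenario2_features_750
        K = kernel_matrix(Z, np.ones(36), KernelSpec(36.0))
        fit = reml_fit(ds.y, ds.x[:, None], K)
        pred = predict_lskm(fit, ds.x[:, None], K)
        assert np.allclose(pred, ds.x * fit.beta[0] + fit.h_hat, atol=1e-10)

    def test_zero_alpha_gives_linear_prediction(self):
        from fkmr.lskm import LskmFit
        fit = LskmFit(beta=np.array([2.0]), alpha=np.zeros(5),
                      h_hat=np.zeros(5), tau=0, sigma2=1, lambda1=1,
                      reml_loglik=0, converged=True)
        pred = predict_lskm(fit, np.ones((3, 1)), np.ones((3, 5)))
        assert np.allclose(pred, 2.0)

    def test_oracle_features_test_quasi_r2(self, scenario2_features_750):
        """Kernel machine on the true signal features predicts well."""
        from fkmr.evaluate import quasi_r2
        from fkmr.kernels import kernel_cross
        from fkmr.simulate import ScenarioConfig, simulate_dataset
        ds = simulate_dataset(ScenarioConfig(scenario=2, n_subjects=1000,
                                             seed=33))
        tr, te = ds.train_index, ds.test_index
        idx = ds.signal_feature_indices
        Ztr, Zte = ds.true_zeta[tr][:, idx], ds.true_zeta[te][:, idx]
        spec = KernelSpec(float(len(idx)))
        K = kernel_matrix(Ztr, np.ones(5), spec)
        fit = reml_fit(ds.y[tr], ds.x[tr][:, None], K)
        pred = predict_lskm(fit, ds.x[te][:, None],
                            kernel_cross(Zte, Ztr, np.ones(5), spec))
        assert quasi_r2(ds.y[te], pred) > 0.8
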