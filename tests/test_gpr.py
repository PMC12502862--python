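"""GP regression: kernel algebra, marginal likelihood, fitting and inversion API."""

import numpy as np
import pytest
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, WhiteKernel

import drivenchain as dc
from drivenchain.fixtures import make_fixture
from drivenchain.gpr import (
    DrivenChainGPR,
    KernelSpec,
    evaluate_inversion,
    fit_inversion,
    invert_map,
    kernel_matrix,
    load_models,
    log_marginal_likelihood,
    r2_score,
    save_models,
)


class TestKernelMatrix:
    def test_single_point_diagonal(self):
        spec = KernelSpec(2.0, 0.3)
        K = kernel_matrix(np.array([[1.0, 2.0]]), None, spec)
        assert K[0, 0] == pytest.approx(1 + 0.3**2)

    def test_distant_points_decorrelate(self):
        spec = KernelSpec(1.0, 0.0)
        K = kernel_matrix(np.array([[0.0]]), np.array([[100.0]]), spec)
        assert K[0, 0] == pytest.approx(0.0, abs=1e-300)

    def test_hand_computed_three_by_three(self):
        # oracle: elementwise evaluation of exp(-d^2/2l^2) + sigma^2 delta
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0]])
        spec = KernelSpec(1.0, 0.1)
        K = kernel_matrix(X, None, spec)
        expected = np.empty((3, 3))
        for i in range(3):
            for j in range(3):
                d2 = np.sum((X[i] - X[j]) ** 2)
                expected[i, j] = np.exp(-d2 / 2) + (0.1**2 if i == j else 0.0)
        assert np.allclose(K, expected, atol=1e-12)
        assert np.allclose(K, K.T)
        assert np.all(np.linalg.eigvalsh(K) > 0)

    def test_cross_set_has_no_noise_term(self):
        X = np.array([[0.0], [1.0]])
        spec = KernelSpec(1.0, 0.5)
        K = kernel_matrix(X, X.copy(), spec)
        assert K[0, 0] == pytest.approx(1.0)  # no sigma^2 between distinct sets

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            kernel_matrix(np.ones((2, 3)), np.ones((2, 2)), KernelSpec(1.0, 0.1))


class TestLogMarginalLikelihood:
    def test_scalar_closed_form(self):
        # n=1, y=m: LML = -1/2 log(1+sigma^2) - 1/2 log(2 pi)
        for sigma in (0.1, 0.7):
            spec = KernelSpec(1.0, sigma, constant_mean=3.0)
            lml = log_marginal_likelihood(np.array([[0.0]]), np.array([3.0]), spec)
            assert lml == pytest.approx(
                -0.5 * np.log(1 + sigma**2) - 0.5 * np.log(2 * np.pi), rel=1e-12
            )

    def test_dense_linear_algebra_oracle(self, rng):
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        spec = KernelSpec(1.3, 0.2, constant_mean=0.4)
        K = kernel_matrix(X, None, spec)
        yc = y - 0.4
        naive = (
            -0.5 * yc @ np.linalg.inv(K) @ yc
            - 0.5 * np.log(np.linalg.det(K))
            - 5 * np.log(2 * np.pi)
        )
        assert log_marginal_likelihood(X, y, spec) == pytest.approx(naive, abs=1e-8)

    def test_matches_sklearn(self, rng):
        X = rng.normal(size=(12, 4))
        y = rng.normal(size=12)
        l, sigma = 0.8, 0.3
        gp = GaussianProcessRegressor(
            RBF(l) + WhiteKernel(sigma**2), optimizer=None, normalize_y=False
        ).fit(X, y)
        ours = log_marginal_likelihood(X, y, KernelSpec(l, sigma, 0.0))
        assert ours == pytest.approx(gp.log_marginal_likelihood_value_, abs=1e-8)

    def test_gradient_matches_finite_differences(self, rng):
        X = rng.normal(size=(8, 2))
        y = rng.normal(size=8)
        theta = np.array([0.2, -1.0])  # log l, log sigma

        def f(t):
            return log_marginal_likelihood(X, y, KernelSpec(np.exp(t[0]), np.exp(t[1])))

        _, grad = log_marginal_likelihood(
            X, y, KernelSpec(np.exp(theta[0]), np.exp(theta[1])), return_grad=True
        )
        eps = 1e-6
        for j in range(2):
            step = np.zeros(2)
            step[j] = eps
            fd = (f(theta + step) - f(theta - step)) / (2 * eps)
            assert grad[j] == pytest.approx(fd, rel=1e-4, abs=1e-7)

    def test_noise_tempers_data_fit(self, rng):
        X = rng.normal(size=(6, 2))
        y = rng.normal(size=6) + 5.0

        def datafit(sigma):
            spec = KernelSpec(1.0, sigma, constant_mean=0.0)
            K = kernel_matrix(X, None, spec)
            yc = y
            return 0.5 * yc @ np.linalg.solve(K, yc)

        assert datafit(1.0) < datafit(0.01)


class TestEstimator:
    def test_posterior_mean_three_point_oracle(self):
        X = np.array([[0.0], [1.0], [2.0]])
        y = np.array([1.0, 2.0, 1.5])
        spec = KernelSpec(1.0, 0.1, constant_mean=float(y.mean()))
        model = DrivenChainGPR(
            length_scale=1.0, noise=0.1, optimize=False, normalize_y=False
        ).fit(X, y)
        Xs = np.array([[0.5], [3.0]])
        K = kernel_matrix(X, None, spec)
        ks = kernel_matrix(Xs, X, spec)
        oracle = y.mean() + ks @ np.linalg.solve(K, y - y.mean())
        assert np.allclose(model.predict(Xs), oracle, atol=1e-10)

    def test_interpolates_training_data_at_small_noise(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.sin(X[:, 0])
        model = DrivenChainGPR(length_scale=1.5, noise=1e-6, optimize=False).fit(X, y)
        assert np.allclose(model.predict(X), y, atol=1e-6)

    def test_far_extrapolation_returns_constant_mean(self, rng):
        X = rng.normal(size=(10, 2))
        y = rng.uniform(2, 3, size=10)
        model = DrivenChainGPR(length_scale=0.5, noise=0.1, optimize=False).fit(X, y)
        far = np.full((1, 2), 1e4)
        assert model.predict(far)[0] == pytest.approx(y.mean(), rel=1e-10)

    def test_constant_target(self):
        X = np.arange(8, dtype=float)[:, None]
        y = np.full(8, 4.2)
        model = DrivenChainGPR(n_restarts=2, random_state=0).fit(X, y)
        assert np.allclose(model.predict(X), 4.2, atol=1e-8)
        assert model.noise_ <= 1e-6  # optimizes toward its lower bound

    def test_hyperparameter_recovery_on_gp_sample(self):
        X, y = make_fixture(
            "gp_toy_dataset",
            {"n": 100, "dim": 2, "length_scale": 1.0, "noise": 0.1},
            seed=3,
        )
        model = DrivenChainGPR(n_restarts=5, random_state=0, normalize_y=False).fit(X, y)
        assert 0.7 <= model.length_scale_ <= 1.3
        assert 0.05 <= model.noise_ <= 0.2

    def test_optimum_matches_sklearn(self):
        X, y = make_fixture(
            "gp_toy_dataset", {"n": 60, "dim": 2, "length_scale": 0.8, "noise": 0.15},
            seed=1,
        )
        ours = DrivenChainGPR(n_restarts=5, random_state=0).fit(X, y)
        sk = GaussianProcessRegressor(
            RBF(1.0, (1e-2, 1e3)) + WhiteKernel(1e-2, (1e-16, 1.0)),
            normalize_y=True,
            n_restarts_optimizer=5,
            random_state=0,
        ).fit(X, y)
        sk_l = sk.kernel_.k1.length_scale
        sk_sigma = np.sqrt(sk.kernel_.k2.noise_level)
        assert ours.length_scale_ == pytest.approx(sk_l, rel=1e-3)
        assert ours.noise_ == pytest.approx(sk_sigma, rel=1e-2)
        assert np.allclose(ours.predict(X), sk.predict(X), atol=1e-6)

    def test_prediction_invariant_under_row_permutation(self, rng):
        X = rng.normal(size=(15, 2))
        y = rng.normal(size=15)
        perm = rng.permutation(15)
        a = DrivenChainGPR(optimize=False, length_scale=1.0, noise=0.2).fit(X, y)
        b = DrivenChainGPR(optimize=False, length_scale=1.0, noise=0.2).fit(X[perm], y[perm])
        Xs = rng.normal(size=(4, 2))
        assert np.allclose(a.predict(Xs), b.predict(Xs), atol=1e-9)

    def test_sklearn_params_contract(self):
        model = DrivenChainGPR(noise=0.2)
        assert model.get_params()["noise"] == 0.2
        model.set_params(noise=0.3)
        assert model.noise == 0.3


class TestR2Score:
    def test_examples(self):
        assert r2_score([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert r2_score([1, 2, 3], [2, 2, 2]) == pytest.approx(0.0)
        assert r2_score([1, 2, 3], [1, 2, 4]) == pytest.approx(0.5)

    def test_errors(self):
        with pytest.raises(ValueError):
            r2_score([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            r2_score([2, 2, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            r2_score([1], [1])


class TestInversionAPI:
    def test_fit_evaluate_and_grid_guard(self, small_dataset, tmp_path):
        from drivenchain.dataset import split_dataset
        from drivenchain.scattering import make_q_grid

        train, test = split_dataset(small_dataset, 0.5, seed=1)
        models = fit_inversion(train, targets=["kappa", "rg2_norm"], n_restarts=1)
        report = evaluate_inversion(models, test)
        assert set(report.table["target"]) == {"kappa", "rg2_norm"}
        assert (report.table["r2"] <= 1).all()

        # persistence round trip preserves predictions exactly
        p = tmp_path / "models.h5"
        save_models(models, p)
        back = load_models(p)
        assert np.allclose(
            back["kappa"].predict(test.F), models["kappa"].predict(test.F)
        )

        # inverting a single map works on the training grid and refuses others
        smap = test.map_for_row(0)
        pred = invert_map(models, smap)
        assert set(pred) == {"kappa", "rg2_norm"}
        other = dc.ensemble_intensity(
            np.zeros((1, 4, 3)) + np.arange(4)[None, :, None],
            make_q_grid(11, 1.0),
        )
        with pytest.raises(ValueError, match="grid"):
            invert_map(models, other)

    def test_unknown_target_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            fit_inversion(small_dataset, targets=["not_a_target"])
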