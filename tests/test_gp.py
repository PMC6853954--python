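import numpy as np
import pytest

from pathwayopt import (
    FitConfig,
    GPHyperparams,
    ValidationError,
    fit_gp,
    fit_gp_arrays,
    kernel,
    log_marginal_likelihood,
    make_design_space,
    posterior,
)
from pathwayopt.gp import augment_model, kernel_matrix
from pathwayopt.landscapes import Observation
from pathwayopt.gridspace import DesignPoint

HP1 = GPHyperparams(lengthscales=(1.0,), signal_variance=2.0, noise_variance=0.1)


class TestKernel:
    def test_zero_distance_gives_signal_variance(self):
        assert kernel([0.3], [0.3], HP1) == pytest.approx(2.0)

    def test_decay_to_zero_at_large_distance(self):
        assert kernel([0.0], [100.0], HP1) < 1e-10

    def test_unit_distance_scalar_arithmetic(self):
        # (1 + sqrt5 + 5/3) * exp(-sqrt5) = 0.523994...
        s5 = np.sqrt(5)
        expected = (1 + s5 + 5 / 3) * np.exp(-s5)
        assert kernel([0.0], [1.0], HP1) == pytest.approx(2.0 * expected, rel=1e-12)
        assert expected == pytest.approx(0.52399, abs=5e-6)

    def test_symmetry_and_dimension_check(self):
        hp = GPHyperparams(lengthscales=(0.5, 2.0), signal_variance=1.0)
        a, b = [0.1, 0.9], [0.7, 0.2]
        assert kernel(a, b, hp) == pytest.approx(kernel(b, a, hp))
        with pytest.raises(ValidationError):
            kernel([0.1], [0.1, 0.2], hp)

    def test_gram_matrices_positive_semidefinite(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            X = rng.uniform(size=(20, 3))
            hp = GPHyperparams(lengthscales=tuple(rng.uniform(0.1, 2.0, 3)),
                               signal_variance=float(rng.uniform(0.5, 3.0)))
            K = kernel_matrix(X, X, hp)
            np.testing.assert_allclose(K, K.T, atol=1e-12)
            assert np.linalg.eigvalsh(K).min() > -1e-9


class TestLogMarginalLikelihood:
    def test_single_point_closed_form(self):
        hp = GPHyperparams(lengthscales=(1.0,), signal_variance=2.0,
                           noise_variance=0.5, constant_mean=3.0)
        got = log_marginal_likelihood(np.array([[0.2]]), np.array([3.0]), hp)
        expected = -0.5 * np.log(2.5) - 0.5 * np.log(2 * np.pi)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_two_point_hand_built_oracle(self):
        hp = GPHyperparams(lengthscales=(1.0,), signal_variance=1.5,
                           noise_variance=0.2)
        X = np.array([[0.0], [0.6]])
        y = np.array([1.0, -0.5])
        k01 = kernel([0.0], [0.6], hp)
        K = np.array([[1.5 + 0.2, k01], [k01, 1.5 + 0.2]])
        expected = (-0.5 * y @ np.linalg.inv(K) @ y
                    - 0.5 * np.log(np.linalg.det(K)) - np.log(2 * np.pi))
        got = log_marginal_likelihood(X, y, hp)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_duplicate_points_remain_finite(self):
        hp = GPHyperparams(lengthscales=(1.0,), signal_variance=1.0,
                           noise_variance=0.0)
        X = np.array([[0.3], [0.3]])
        y = np.array([1.0, 1.0])
        assert np.isfinite(log_marginal_likelihood(X, y, hp))


class TestFit:
    def test_identical_values_yield_constant_posterior(self, small_space):
        obs = [Observation.from_replicates(p, [4.2])
               for p in small_space.enumerate_points()]
        model = fit_gp(obs, small_space)
        means, _ = posterior(model, np.array([[0.25, 0.75], [0.9, 0.1]]))
        np.testing.assert_allclose(means, 4.2, atol=1e-8)

    def test_white_noise_attributed_to_noise_variance(self):
        rng = np.random.default_rng(8)
        X = rng.uniform(size=(120, 2))
        y = rng.normal(0.0, 1.0, size=120)  # no signal at all
        model = fit_gp_arrays(X, y, FitConfig(restarts=4, seed=1))
        # in standardized units the sample variance is 1 by construction;
        # nearly all of it should be explained as noise
        assert model.hyperparams.noise_variance > 0.5

    def test_too_few_points_fall_back_to_prior_defaults(self):
        X = np.array([[0.1, 0.2, 0.3]])
        model = fit_gp_arrays(X, np.array([2.0]))
        assert any("prior-default" in w for w in model.warnings_log)

    def test_fit_requires_observations(self, small_space):
        with pytest.raises(ValidationError):
            fit_gp([], small_space)


class TestPosterior:
    def _toy_model(self, noise=1e-10):
        X = np.array([[0.0], [0.25], [0.5], [0.75], [1.0]])
        y = np.array([0.0, 0.8, 1.0, 0.3, -0.4])
        hp = GPHyperparams(lengthscales=(0.3,), signal_variance=1.2,
                           noise_variance=noise)
        y_mean, y_sd = float(y.mean()), float(y.std())
        from pathwayopt.gp import _solve_model
        return _solve_model(hp, X, (y - y_mean) / y_sd, y_mean, y_sd,
                            "matern52"), X, y

    def test_interpolates_training_data_in_zero_noise_limit(self):
        model, X, y = self._toy_model()
        means, variances = posterior(model, X)
        np.testing.assert_allclose(means, y, atol=1e-6)
        assert variances.max() < 1e-6

    def test_reverts_to_prior_far_from_data(self):
        model, X, y = self._toy_model(noise=1e-6)
        means, variances = posterior(model, np.array([[50.0]]))
        assert means[0] == pytest.approx(y.mean(), abs=1e-6)
        assert variances[0] == pytest.approx(
            1.2 * y.std() ** 2, rel=1e-6)

    def test_matches_independent_dense_linear_algebra(self):
        model, X, y = self._toy_model(noise=0.05)
        Xq = np.linspace(0, 1, 17)[:, None]
        means, variances = posterior(model, Xq)
        # brute-force oracle with explicit matrix inversion
        hp = model.hyperparams
        ys = (y - y.mean()) / y.std()
        K = kernel_matrix(X, X, hp) + hp.noise_variance * np.eye(5)
        Ks = kernel_matrix(Xq, X, hp)
        Kinv = np.linalg.inv(K)
        mu = Ks @ Kinv @ ys
        var = hp.signal_variance - np.einsum("ij,jk,ik->i", Ks, Kinv, Ks)
        np.testing.assert_allclose(means, y.mean() + y.std() * mu, rtol=1e-8)
        np.testing.assert_allclose(variances, y.std() ** 2 * var, rtol=1e-7)

    def test_matches_sklearn_cross_check(self):
        # independent reference implementation with frozen hyperparameters
        sklearn_gp = pytest.importorskip("sklearn.gaussian_process")
        from sklearn.gaussian_process.kernels import Matern, ConstantKernel

        model, X, y = self._toy_model(noise=0.03)
        hp = model.hyperparams
        k = ConstantKernel(hp.signal_variance, "fixed") * Matern(
            length_scale=hp.lengthscales[0], length_scale_bounds="fixed", nu=2.5)
        ref = sklearn_gp.GaussianProcessRegressor(
            kernel=k, alpha=hp.noise_variance, optimizer=None, normalize_y=False)
        ys = (y - y.mean()) / y.std()
        ref.fit(X, ys)
        Xq = np.linspace(0, 1, 9)[:, None]
        mu_ref, sd_ref = ref.predict(Xq, return_std=True)
        means, variances = posterior(model, Xq)
        np.testing.assert_allclose(means, y.mean() + y.std() * mu_ref, rtol=1e-6)
        np.testing.assert_allclose(np.sqrt(variances), y.std() * sd_ref,
                                   rtol=1e-5)

    def test_variance_bounded_by_prior_and_shrinks_with_data(self):
        model, X, y = self._toy_model(noise=0.05)
        hp = model.hyperparams
        Xq = np.linspace(0, 1, 31)[:, None]
        _, var_before = posterior(model, Xq)
        prior_var = y.std() ** 2 * (hp.signal_variance + hp.noise_variance)
        assert (var_before <= prior_var + 1e-12).all()
        grown = augment_model(model, np.array([[0.6]]), np.array([0.5]))
        _, var_after = posterior(grown, Xq)
        assert (var_after <= var_before + 1e-10).all()

    def test_one_point_update_matches_closed_form(self):
        # adding one observation with frozen hyperparameters must follow the
        # scalar noise-weighted shrinkage formula at the observed site
        model, X, y = self._toy_model(noise=0.05)
        hp = model.hyperparams
        xq = np.array([[0.6]])
        mu0, var0 = posterior(model, xq)
        value = 0.5
        grown = augment_model(model, xq, np.array([value]))
        mu1, var1 = posterior(grown, xq)
        noise_raw = hp.noise_variance * y.std() ** 2
        expected_mu = mu0[0] + var0[0] / (var0[0] + noise_raw) * (value - mu0[0])
        expected_var = var0[0] - var0[0] ** 2 / (var0[0] + noise_raw)
        assert mu1[0] == pytest.approx(expected_mu, rel=1e-8)
        assert var1[0] == pytest.approx(expected_var, rel=1e-6, abs=1e-12)

    def test_affine_output_equivariance(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(size=(30, 2))
        y = np.sin(4 * X[:, 0]) + X[:, 1]
        a, b = 2.5, -7.0
        m1 = fit_gp_arrays(X, y, FitConfig(restarts=3, seed=5))
        m2 = fit_gp_arrays(X, a * y + b, FitConfig(restarts=3, seed=5))
        Xq = rng.uniform(size=(10, 2))
        mu1, var1 = posterior(m1, Xq)
        mu2, var2 = posterior(m2, Xq)
        np.testing.assert_allclose(mu2, a * mu1 + b, rtol=1e-6, atol=1e-8)
        np.testing.assert_allclose(var2, a**2 * var1, rtol=1e-6, atol=1e-10)

    def test_unfitted_model_raises_state_error(self):
        from pathwayopt.gp import GPModel
        model = GPModel(hyperparams=HP1, train_points=np.zeros((1, 1)),
                        train_values=np.zeros(1), y_mean=0.0, y_sd=1.0)
        with pytest.raises(RuntimeError, match="not fitted"):
            posterior(model, np.array([[0.0]]))


class TestObservationsInterface:
    def test_repeated_control_kept_as_separate_rows(self, cube24):
        control = DesignPoint((12, 12, 12))
        obs = [Observation.from_replicates(control, [5.0], round_index=r)
               for r in range(3)]
        obs += [Observation.from_replicates(DesignPoint((c, c, c)), [float(c)])
                for c in (1, 5, 20, 24, 8, 16)]
        model = fit_gp(obs, cube24, FitConfig(restarts=2))
        assert model.n_train() == 9
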