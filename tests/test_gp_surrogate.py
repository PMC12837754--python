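"""ARD GP regression, linear baseline, and accuracy metrics."""

import numpy as np
import pytest

from mvsens.gp_surrogate import (
    ZeroVarianceError,
    ard_kernel,
    cv_init_lengthscale,
    default_init_grid,
    fit_gp,
    fit_linear,
    kernel_matrix,
    log_marginal_likelihood,
    mape,
    predict_linear,
    predict_mean,
    r_squared,
)


class TestKernel:
    def test_identical_inputs_give_one(self):
        x = np.array([1.0, 2.0, 3.0])
        assert ard_kernel(x, x, np.ones(3)) == 1.0

    def test_unit_distance_closed_form(self):
        assert ard_kernel(np.array([0.0]), np.array([1.0]), np.array([1.0])) == \
            pytest.approx(np.exp(-0.5))

    def test_decay_to_zero(self):
        assert ard_kernel(np.array([0.0]), np.array([100.0]), np.array([1.0])) < 1e-300 or \
            ard_kernel(np.array([0.0]), np.array([100.0]), np.array([1.0])) == 0.0

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ard_kernel(np.zeros(2), np.zeros(3), np.ones(3))
        with pytest.raises(ValueError, match="positive"):
            ard_kernel(np.zeros(2), np.zeros(2), np.array([1.0, -1.0]))

    def test_gram_matrix_symmetric_unit_diagonal_cauchy_schwarz(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 5))
        l = rng.uniform(0.5, 2.0, size=5)
        K = kernel_matrix(X, X, l)
        np.testing.assert_allclose(K, K.T, atol=1e-14)
        np.testing.assert_allclose(np.diag(K), 1.0, atol=1e-14)
        assert np.all(K**2 <= np.outer(np.diag(K), np.diag(K)) + 1e-14)


class TestEvidence:
    def test_single_point_closed_form(self):
        got = log_marginal_likelihood([[0.0]], [0.0], [1.0], sigma2=1e-4)
        want = -0.5 * np.log(1 + 1e-4) - 0.5 * np.log(2 * np.pi)
        assert got == pytest.approx(want, abs=1e-12)

    def test_invariant_under_row_permutation(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(25, 3))
        y = rng.normal(size=25)
        l = np.array([1.0, 2.0, 0.7])
        perm = rng.permutation(25)
        a = log_marginal_likelihood(X, y, l)
        b = log_marginal_likelihood(X[perm], y[perm], l)
        assert a == pytest.approx(b, rel=1e-10)

    def test_peaks_near_generative_lengthscale(self):
        rng = np.random.default_rng(2)
        X = np.linspace(0, 10, 60)[:, None]
        true_l = np.array([1.5])
        K = kernel_matrix(X, X, true_l) + 1e-8 * np.eye(60)
        y = np.linalg.cholesky(K) @ rng.normal(size=60)
        good = log_marginal_likelihood(X, y, true_l)
        assert good > log_marginal_likelihood(X, y, true_l * 10)
        assert good > log_marginal_likelihood(X, y, true_l / 10)


class TestFitPredict:
    def test_noise_free_interpolation(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, (30, 3))
        y = np.sin(3 * X[:, 0]) + X[:, 1] ** 2
        gp = fit_gp(X, y, np.full(3, 0.5), sigma2=1e-10, n_restarts=0, maxiter=0)
        assert np.abs(predict_mean(gp, X) - y).max() < 1e-6

    def test_far_field_reverts_to_training_mean(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 1, (20, 2))
        y = rng.uniform(5, 10, 20)
        gp = fit_gp(X, y, np.full(2, 0.3), n_restarts=0, maxiter=0)
        far = predict_mean(gp, np.array([[100.0, -50.0]]))
        assert far[0] == pytest.approx(y.mean(), abs=1e-8)

    def test_constant_target_degenerate_guard(self):
        X = np.arange(10, dtype=float)[:, None]
        y = np.full(10, 3.3)
        gp = fit_gp(X, y, np.array([1.0]))
        pred = predict_mean(gp, X)
        np.testing.assert_allclose(pred, 3.3)
        assert r_squared(y, pred) == 1.0  # convention guard

    def test_sine_regression_generalizes(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 2 * np.pi, (30, 1))
        y = np.sin(X[:, 0])
        gp = fit_gp(X, y, np.array([1.0]), seed=0)
        Xs = np.linspace(0.1, 2 * np.pi - 0.1, 100)[:, None]
        assert r_squared(np.sin(Xs[:, 0]), predict_mean(gp, Xs)) > 0.99

    def test_fit_deterministic_for_equal_seeds(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(0, 1, (25, 2))
        y = X[:, 0] ** 2 + np.cos(X[:, 1])
        l1 = fit_gp(X, y, np.array([0.5, 0.5]), seed=11).lengthscales
        l2 = fit_gp(X, y, np.array([0.5, 0.5]), seed=11).lengthscales
        np.testing.assert_array_equal(l1, l2)

    def test_prediction_invariant_to_training_permutation(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(0, 1, (30, 2))
        y = X[:, 0] + np.sin(4 * X[:, 1])
        perm = rng.permutation(30)
        l = np.array([0.4, 0.4])
        gp1 = fit_gp(X, y, l, n_restarts=0, maxiter=0)
        gp2 = fit_gp(X[perm], y[perm], l, n_restarts=0, maxiter=0)
        Xs = rng.uniform(0, 1, (15, 2))
        np.testing.assert_allclose(
            predict_mean(gp1, Xs), predict_mean(gp2, Xs), atol=1e-8
        )

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(8)
        gp = fit_gp(rng.normal(size=(10, 3)), rng.normal(size=10),
                    np.ones(3), n_restarts=0, maxiter=0)
        with pytest.raises(ValueError, match="columns"):
            predict_mean(gp, np.zeros((2, 4)))


class TestLinearBaseline:
    def test_exactly_linear_data_recovered(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(50, 4))
        y = 2.0 + X @ np.array([1.0, -2.0, 0.5, 3.0])
        m = fit_linear(X, y)
        assert m.intercept == pytest.approx(2.0, abs=1e-9)
        assert r_squared(y, predict_linear(m, X)) == pytest.approx(1.0)

    def test_pure_noise_has_near_zero_r2(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(2000, 3))
        y = rng.normal(size=2000)
        m = fit_linear(X, y)
        assert abs(r_squared(y, predict_linear(m, X))) < 0.05

    def test_duplicated_column_warns_rank_deficiency(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(30, 2))
        X = np.column_stack([X, X[:, 0]])
        with pytest.warns(RuntimeWarning, match="rank deficient"):
            fit_linear(X, X[:, 0] + 1.0)


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 5.0])
        assert r_squared(y, y) == 1.0
        assert mape(y, y) == 0.0

    def test_hand_computed_r2(self):
        assert r_squared([1.0, 2.0, 3.0], [1.0, 2.0, 4.0]) == pytest.approx(0.5)

    def test_single_term_mape(self):
        assert mape([2.0], [1.0]) == pytest.approx(0.5)

    def test_zero_variance_target_is_error(self):
        with pytest.raises(ZeroVarianceError):
            r_squared([2.0, 2.0], [1.0, 3.0])

    def test_mape_excludes_near_zero_targets(self):
        y = np.array([0.0, 4.0])
        yhat = np.array([1.0, 2.0])
        assert mape(y, yhat) == pytest.approx(0.5)


class TestCVInit:
    def test_single_candidate_returned_unchanged(self):
        X = np.random.default_rng(0).normal(size=(20, 2))
        y = X[:, 0]
        init = cv_init_lengthscale(X, y, [np.array([2.0, 3.0])])
        np.testing.assert_array_equal(init, [2.0, 3.0])

    def test_good_candidate_beats_terrible_one(self):
        rng = np.random.default_rng(12)
        X = rng.uniform(0, 2 * np.pi, (60, 1))
        y = np.sin(X[:, 0])
        good, terrible = np.array([1.0]), np.array([1e-4])
        init = cv_init_lengthscale(X, y, [terrible, good], seed=0)
        np.testing.assert_array_equal(init, good)

    def test_fold_assignment_deterministic(self):
        rng = np.random.default_rng(13)
        X = rng.uniform(0, 1, (40, 2))
        y = X[:, 0] + 0.3 * X[:, 1] ** 2
        cands = default_init_grid(X, (0.1, 1.0, 10.0))
        a = cv_init_lengthscale(X, y, cands, seed=5)
        b = cv_init_lengthscale(X, y, cands, seed=5)
        np.testing.assert_array_equal(a, b)
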