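import numpy as np
import pytest

from dlonmf import (
    Hyperparameters,
    NonNegativityError,
    ParameterError,
    ShapeError,
    UndefinedMetricError,
    build_knn_graph,
    fit_dlonmf,
    fit_nmf,
    generate_planted,
    gradients,
    init_factors,
    objective,
    reconstruction_pcc,
    relative_error,
    update_step,
)


def lee_seung_step(X, U, V, eps=1e-10):
    """Independent plain-NMF oracle: elementwise loops, no linear algebra
    shared with the implementation beyond matmul."""
    XVt = X @ V.T
    UVVt = U @ V @ V.T
    U_new = np.empty_like(U)
    for i in range(U.shape[0]):
        for a in range(U.shape[1]):
            U_new[i, a] = U[i, a] * XVt[i, a] / (UVVt[i, a] + eps)
    UtX = U_new.T @ X
    UtUV = U_new.T @ U_new @ V
    V_new = np.empty_like(V)
    for a in range(V.shape[0]):
        for j in range(V.shape[1]):
            V_new[a, j] = V[a, j] * UtX[a, j] / (UtUV[a, j] + eps)
    return U_new, V_new


def random_instance(seed, m=6, n=5, k=2):
    rng = np.random.default_rng(seed)
    X = rng.random((m, n)) * 3.0
    fg = build_knn_graph(rng.random((m, 4)), 2)
    sg = build_knn_graph(rng.random((n, 4)), 2)
    U = rng.random((m, k)) + 0.1
    V = rng.random((k, n)) + 0.1
    return X, fg, sg, U, V


class TestInitFactors:
    def test_deterministic_per_seed(self):
        a = init_factors(4, 3, 2, seed=9, scale=1.0)
        b = init_factors(4, 3, 2, seed=9, scale=1.0)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
        c = init_factors(4, 3, 2, seed=10, scale=1.0)
        assert not np.array_equal(a[0], c[0])

    def test_shapes_and_positivity(self):
        U, V = init_factors(4, 3, 2, seed=0, scale="auto", x_mean=2.0)
        assert U.shape == (4, 2) and V.shape == (2, 3)
        assert (U > 0).all() and (V > 0).all()

    def test_rank_exceeding_dims_rejected(self):
        with pytest.raises(ParameterError):
            init_factors(4, 3, 4, seed=0, scale=1.0)


class TestObjective:
    def test_perfect_reconstruction_zero_weights(self, rng):
        U = rng.random((5, 2))
        V = rng.random((2, 4))
        hp = Hyperparameters(k=2)
        b = objective(U @ V, U, V, None, None, hp)
        assert b.total == pytest.approx(0.0, abs=1e-20)

    def test_zero_factors_give_norm_squared(self, rng):
        X = rng.random((5, 4))
        b = objective(X, np.zeros((5, 2)), np.zeros((2, 4)), None, None, Hyperparameters(k=2))
        assert b.total == pytest.approx(float(np.linalg.norm(X) ** 2))

    def test_hand_computed_fit_term(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        U = np.array([[1.0], [0.0]])
        V = np.array([[1.0, 0.0]])
        b = objective(X, U, V, None, None, Hyperparameters(k=1))
        assert b.fit == pytest.approx(1.0)

    def test_terms_sum_to_total(self):
        X, fg, sg, U, V = random_instance(3)
        hp = Hyperparameters(
            k=2, lambda_v=0.1, lambda_u=0.2, gamma_feat=0.3,
            gamma_sample=0.4, beta_u=0.5, beta_v=0.6,
        )
        b = objective(X, U, V, fg, sg, hp)
        parts = (
            b.fit + b.ridge_v + b.ridge_u + b.graph_feat
            + b.graph_sample + b.orth_u + b.orth_v
        )
        assert b.total == pytest.approx(parts, rel=1e-9)
        assert min(b.fit, b.ridge_v, b.ridge_u, b.orth_u, b.orth_v) >= 0
        assert b.graph_feat >= -1e-12 and b.graph_sample >= -1e-12

    def test_shape_mismatch_named(self, rng):
        with pytest.raises(ShapeError):
            objective(rng.random((5, 4)), rng.random((5, 2)),
                      rng.random((2, 3)), None, None, Hyperparameters(k=2))


class TestGradients:
    @pytest.mark.parametrize("seed", range(5))
    def test_finite_difference_agreement(self, seed):
        X, fg, sg, U, V = random_instance(seed)
        hp = Hyperparameters(
            k=2, lambda_v=0.05, lambda_u=0.1, gamma_feat=0.2,
            gamma_sample=0.15, beta_u=0.3, beta_v=0.25,
        )
        dU, dV = gradients(X, U, V, fg, sg, hp)
        h = 1e-6

        def total(Uv, Vv):
            return objective(X, Uv, Vv, fg, sg, hp).total

        for idx in np.ndindex(U.shape):
            Up, Um = U.copy(), U.copy()
            Up[idx] += h
            Um[idx] -= h
            fd = (total(Up, V) - total(Um, V)) / (2 * h)
            assert dU[idx] == pytest.approx(fd, rel=1e-4, abs=1e-6)
        for idx in np.ndindex(V.shape):
            Vp, Vm = V.copy(), V.copy()
            Vp[idx] += h
            Vm[idx] -= h
            fd = (total(U, Vp) - total(U, Vm)) / (2 * h)
            assert dV[idx] == pytest.approx(fd, rel=1e-4, abs=1e-6)

    def test_zero_at_exact_factorization(self, rng):
        U = rng.random((5, 2))
        V = rng.random((2, 4))
        dU, dV = gradients(U @ V, U, V, None, None, Hyperparameters(k=2))
        assert np.allclose(dU, 0.0, atol=1e-12)
        assert np.allclose(dV, 0.0, atol=1e-12)

    def test_orthonormal_columns_are_orthogonality_fixed_point(self):
        # U with orthonormal columns: the beta_u term contributes nothing
        U = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]])
        V = np.array([[1.0, 2.0], [3.0, 4.0]])
        hp = Hyperparameters(k=2, beta_u=2.0)
        dU, _ = gradients(U @ V, U, V, None, None, hp)
        assert np.allclose(dU, 0.0, atol=1e-12)


class TestUpdateStep:
    def test_exact_factorization_is_fixed_point(self, rng):
        U = rng.random((5, 2)) + 0.1
        V = rng.random((2, 4)) + 0.1
        X = U @ V
        U2, V2 = update_step(X, U, V, None, None, Hyperparameters(k=2))
        assert np.allclose(U2, U, rtol=1e-8)
        assert np.allclose(V2, V, rtol=1e-8)

    @pytest.mark.parametrize("seed", range(3))
    def test_reduces_to_lee_seung_when_weights_zero(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.random((5, 4)) * 2.0
        U = rng.random((5, 2)) + 0.1
        V = rng.random((2, 4)) + 0.1
        U_ref, V_ref = lee_seung_step(X, U, V)
        U_new, V_new = update_step(X, U, V, None, None, Hyperparameters(k=2))
        assert np.allclose(U_new, U_ref, rtol=1e-12, atol=0)
        assert np.allclose(V_new, V_ref, rtol=1e-12, atol=0)

    def test_zero_entries_stay_zero(self, rng):
        U = rng.random((5, 2)) + 0.1
        V = rng.random((2, 4)) + 0.1
        U[2, 1] = 0.0
        X = rng.random((5, 4))
        U2, _ = update_step(X, U, V, None, None, Hyperparameters(k=2))
        assert U2[2, 1] == 0.0

    def test_negative_input_rejected(self, rng):
        U = rng.random((5, 2))
        U[0, 0] = -0.5
        with pytest.raises(NonNegativityError):
            update_step(rng.random((5, 4)), U, rng.random((2, 4)), None, None,
                        Hyperparameters(k=2))

    def test_nonnegativity_with_all_terms_active(self):
        X, fg, sg, U, V = random_instance(11)
        hp = Hyperparameters(
            k=2, lambda_v=1.0, lambda_u=1.0, gamma_feat=1.0,
            gamma_sample=1.0, beta_u=1.0, beta_v=1.0,
        )
        for _ in range(50):
            U, V = update_step(X, U, V, fg, sg, hp)
            assert (U >= 0).all() and (V >= 0).all()


class TestFitDlonmf:
    def test_noiseless_planted_fit_converges(self, planted_small):
        model = fit_nmf(planted_small.X, k=3, n_iter=500, seed=0)
        fit_term = model.objective_history[-1].fit
        norm_sq = float(np.linalg.norm(planted_small.X.values) ** 2)
        assert fit_term <= 1e-6 * norm_sq

    @pytest.mark.parametrize("weight", [0.0, 0.01, 1.0])
    def test_monotone_objective_without_orthogonality(self, weight):
        for seed in range(5):
            X, fg, sg, _, _ = random_instance(seed, m=10, n=8)
            hp = Hyperparameters(
                k=2, lambda_v=weight, lambda_u=weight, gamma_feat=weight,
                gamma_sample=weight, n_iter=100, seed=seed,
            )
            model = fit_dlonmf(X, fg, sg, hp)
            totals = np.array([b.total for b in model.objective_history])
            assert (np.diff(totals) <= 1e-9 * np.abs(totals[:-1]) + 1e-12).all()

    def test_objective_decreases_with_orthogonality_on(self):
        X, fg, sg, _, _ = random_instance(21, m=10, n=8)
        hp = Hyperparameters(
            k=2, lambda_v=0.01, lambda_u=0.01, gamma_feat=0.01,
            gamma_sample=0.01, beta_u=0.5, beta_v=0.5, n_iter=100, seed=3,
        )
        model = fit_dlonmf(X, fg, sg, hp)
        assert model.objective_history[-1].total < model.objective_history[0].total

    def test_zero_iterations_returns_initialization(self, small_matrix):
        model = fit_dlonmf(small_matrix, None, None, Hyperparameters(k=2, n_iter=0))
        assert model.converged_at == 0
        assert len(model.objective_history) == 1

    def test_history_length_matches_iterations(self, small_matrix):
        model = fit_dlonmf(small_matrix, None, None, Hyperparameters(k=2, n_iter=7))
        assert model.converged_at == 7
        assert len(model.objective_history) == 8

    def test_early_stop_on_tol(self, small_matrix):
        # noisy data: the objective plateaus at a positive residual, so the
        # relative change eventually drops below tol
        hp = Hyperparameters(k=2, n_iter=5000, tol=1e-6, seed=0)
        model = fit_dlonmf(small_matrix, None, None, hp)
        assert model.converged_at < 5000
        assert len(model.objective_history) == model.converged_at + 1

    def test_rank_too_large_rejected(self, small_matrix):
        with pytest.raises(ParameterError):
            fit_dlonmf(small_matrix, None, None, Hyperparameters(k=6))

    def test_negative_matrix_rejected(self, rng):
        with pytest.raises(NonNegativityError):
            fit_dlonmf(rng.normal(size=(5, 4)), None, None, Hyperparameters(k=2))

    def test_u_column_normalization_keeps_reconstruction(self, planted_small):
        hp = Hyperparameters(k=3, n_iter=200, seed=0, normalize="u-columns")
        model = fit_dlonmf(planted_small.X, None, None, hp)
        norms = np.linalg.norm(model.U, axis=0)
        assert np.allclose(norms, 1.0)
        assert reconstruction_pcc(planted_small.X, model.U, model.V) > 0.99


class TestFitNmf:
    def test_bitwise_equal_to_zero_weight_dlonmf(self, small_matrix):
        a = fit_nmf(small_matrix, k=2, n_iter=30, seed=4)
        b = fit_dlonmf(small_matrix, None, None,
                       Hyperparameters(k=2, n_iter=30, seed=4))
        assert np.array_equal(a.U, b.U)
        assert np.array_equal(a.V, b.V)

    def test_rank_one_matrix_fits_exactly(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([0.5, 1.5, 2.5, 3.5])
        X = np.outer(a, b)
        model = fit_nmf(X, k=1, n_iter=200, seed=0)
        assert model.objective_history[-1].fit == pytest.approx(0.0, abs=1e-8)

    def test_zero_row_drives_loading_to_zero(self, rng):
        X = rng.random((6, 5)) + 0.5
        X[2, :] = 0.0
        model = fit_nmf(X, k=2, n_iter=300, seed=1)
        assert np.abs(model.U[2]).max() < 1e-3 * np.abs(model.U).max()


class TestReconstructionMetrics:
    def test_pcc_perfect_and_anticorrelated(self, rng):
        U = rng.random((4, 2))
        V = rng.random((2, 3))
        X = U @ V
        assert reconstruction_pcc(X, U, V) == pytest.approx(1.0)
        # UV = c - X has correlation -1 with X; check via the raw definition
        c = X.max() + 1.0
        flipped = c - X
        r = np.corrcoef(X.ravel(), flipped.ravel())[0, 1]
        assert r == pytest.approx(-1.0)

    def test_pcc_matches_four_point_closed_form(self):
        X = np.array([[1.0, 2.0], [3.0, 4.0]])
        U = np.array([[1.0, 0.0], [0.0, 1.0]])
        V = np.array([[1.0, 2.0], [3.0, 5.0]])
        expected = np.corrcoef([1, 2, 3, 4], [1, 2, 3, 5])[0, 1]
        assert reconstruction_pcc(X, U, V) == pytest.approx(expected, rel=1e-12)

    def test_pcc_constant_matrix_rejected(self):
        with pytest.raises(UndefinedMetricError):
            reconstruction_pcc(np.ones((3, 3)), np.ones((3, 1)), np.ones((1, 3)))

    def test_relative_error_examples(self, rng):
        X = np.eye(2)
        assert relative_error(X, np.zeros((2, 1)), np.zeros((1, 2))) == pytest.approx(2.0)
        U = rng.random((3, 2))
        V = rng.random((2, 3))
        X = rng.random((3, 3))
        brute = sum(
            (X[i, j] - (U @ V)[i, j]) ** 2 for i in range(3) for j in range(3)
        )
        assert relative_error(X, U, V) == pytest.approx(brute, rel=1e-12)

    def test_normalized_variant(self, rng):
        X = rng.random((3, 3)) + 0.5
        err = relative_error(X, np.zeros((3, 1)), np.zeros((1, 3)), normalized=True)
        assert err == pytest.approx(1.0)
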