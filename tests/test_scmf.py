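import numpy as np
import pytest

from mirlink.evaluation import auc_rank
from mirlink.scmf import (
    SCMFParams,
    fit_scmf,
    grad_u,
    grad_v,
    predict_scores,
    scmf_objective,
    update_row_u,
    update_row_v,
)


def numeric_grad_u(i, U, V, A, SM, SD, params, h=1e-6):
    g = np.zeros(U.shape[1])
    for k in range(U.shape[1]):
        Up, Um = U.copy(), U.copy()
        Up[i, k] += h
        Um[i, k] -= h
        g[k] = (
            scmf_objective(Up, V, A, SM, SD, params) - scmf_objective(Um, V, A, SM, SD, params)
        ) / (2 * h)
    return g


def numeric_grad_v(j, U, V, A, SM, SD, params, h=1e-6):
    g = np.zeros(V.shape[1])
    for k in range(V.shape[1]):
        Vp, Vm = V.copy(), V.copy()
        Vp[j, k] += h
        Vm[j, k] -= h
        g[k] = (
            scmf_objective(U, Vp, A, SM, SD, params) - scmf_objective(U, Vm, A, SM, SD, params)
        ) / (2 * h)
    return g


def random_instance(rng, nm=6, nd=5, r=3):
    A = rng.standard_normal((nm, nd))
    SM = rng.random((nm, nm))
    SD = rng.random((nd, nd))
    U = rng.standard_normal((nm, r))
    V = rng.standard_normal((nd, r))
    return A, SM, SD, U, V


class TestObjective:
    def test_zero_factors(self, rng):
        A = rng.random((4, 3))
        params = SCMFParams(rank=2, theta=1.0, sigma=1.0)
        U, V = np.zeros((4, 2)), np.zeros((3, 2))
        SM, SD = np.ones((4, 4)), np.ones((3, 3))
        assert scmf_objective(U, V, A, SM, SD, params) == pytest.approx(0.5 * np.sum(A**2))

    def test_exact_factorization_unregularized(self, rng):
        U = rng.random((4, 2))
        V = rng.random((3, 2))
        A = U @ V.T
        params = SCMFParams(rank=2, theta=0.0, sigma=0.0)
        assert scmf_objective(U, V, A, np.ones((4, 4)), np.ones((3, 3)), params) == pytest.approx(0.0, abs=1e-12)

    def test_all_ones_hand_value(self):
        # 2x2, rank 1, every matrix filled with ones, theta = sigma = 1:
        # data term 0 (A=UV^T=1), L2 = 1/2*(2+2) = 2, similarity terms 0
        params = SCMFParams(rank=1, theta=1.0, sigma=1.0)
        U = np.ones((2, 1))
        V = np.ones((2, 1))
        A = np.ones((2, 2))
        S = np.ones((2, 2))
        assert scmf_objective(U, V, A, S, S, params) == pytest.approx(2.0)

    def test_similarity_penalty_hand_value(self):
        # u rows [0] and [1], SM all ones: sum_ij ||ui-uj||^2 SMij = 2 (pairs
        # (0,1) and (1,0)); with sigma=2 contributes sigma/2*2 = 2
        params = SCMFParams(rank=1, theta=0.0, sigma=2.0)
        U = np.array([[0.0], [1.0]])
        V = np.zeros((2, 1))
        A = np.zeros((2, 2))
        S = np.ones((2, 2))
        assert scmf_objective(U, V, A, S, np.zeros((2, 2)), params) == pytest.approx(2.0)

    def test_shape_mismatch(self, rng):
        params = SCMFParams(rank=2)
        with pytest.raises(ValueError):
            scmf_objective(np.zeros((3, 2)), np.zeros((4, 2)), np.zeros((3, 3)), np.eye(3), np.eye(4), params)


class TestGradients:
    @pytest.mark.parametrize("seed", range(5))
    def test_grad_u_matches_central_difference(self, seed):
        rng = np.random.default_rng(seed)
        A, SM, SD, U, V = random_instance(rng)
        params = SCMFParams(rank=3, theta=0.7, sigma=1.3)
        for i in (0, 3):
            g = grad_u(i, U, V, A, SM, params)
            gn = numeric_grad_u(i, U, V, A, SM, SD, params)
            np.testing.assert_allclose(g, gn, rtol=1e-5, atol=1e-7)

    @pytest.mark.parametrize("seed", range(5))
    def test_grad_v_matches_central_difference(self, seed):
        rng = np.random.default_rng(seed)
        A, SM, SD, U, V = random_instance(rng)
        params = SCMFParams(rank=3, theta=0.7, sigma=1.3)
        for j in (0, 4):
            g = grad_v(j, U, V, A, SD, params)
            gn = numeric_grad_v(j, U, V, A, SM, SD, params)
            np.testing.assert_allclose(g, gn, rtol=1e-5, atol=1e-7)


class TestRowUpdates:
    def test_sigma_zero_theta_zero_least_squares(self, rng):
        # with V^T V = I the update reduces to the projected row A(i,:)V
        A = rng.standard_normal((5, 4))
        V, _ = np.linalg.qr(rng.standard_normal((4, 3)))
        U = rng.standard_normal((5, 3))
        params = SCMFParams(rank=3, theta=0.0, sigma=0.0)
        got = update_row_u(0, U, V, A, np.zeros((5, 5)), params)
        np.testing.assert_allclose(got, A[0, :] @ V, atol=1e-10)

    def test_v_update_least_squares(self, rng):
        A = rng.standard_normal((5, 4))
        U, _ = np.linalg.qr(rng.standard_normal((5, 3)))
        V = rng.standard_normal((4, 3))
        params = SCMFParams(rank=3, theta=0.0, sigma=0.0)
        got = update_row_v(0, U, V, A, np.zeros((4, 4)), params)
        np.testing.assert_allclose(got, A[:, 0] @ U, atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_update_decreases_objective(self, seed):
        rng = np.random.default_rng(seed)
        A, SM, SD, U, V = random_instance(rng)
        params = SCMFParams(rank=3, theta=0.5, sigma=0.8)
        before = scmf_objective(U, V, A, SM, SD, params)
        for i in range(U.shape[0]):
            U[i] = update_row_u(i, U, V, A, SM, params)
            after = scmf_objective(U, V, A, SM, SD, params)
            assert after <= before + 1e-9
            before = after

    @pytest.mark.parametrize("seed", range(5))
    def test_updated_row_has_zero_gradient(self, seed):
        rng = np.random.default_rng(seed)
        A, SM, SD, U, V = random_instance(rng)
        params = SCMFParams(rank=3, theta=0.5, sigma=0.8)
        for i in range(U.shape[0]):
            U[i] = update_row_u(i, U, V, A, SM, params)
            assert np.linalg.norm(grad_u(i, U, V, A, SM, params)) < 1e-8
        for j in range(V.shape[0]):
            V[j] = update_row_v(j, U, V, A, SD, params)
            assert np.linalg.norm(grad_v(j, U, V, A, SD, params)) < 1e-8

    def test_singular_system_errors(self):
        # theta = 0 with rank-deficient V makes the system singular
        U = np.zeros((2, 2))
        V = np.zeros((3, 2))
        A = np.zeros((2, 3))
        params = SCMFParams(rank=2, theta=0.0, sigma=0.0)
        with pytest.raises(np.linalg.LinAlgError, match="u\\[0\\]"):
            update_row_u(0, U, V, A, np.zeros((2, 2)), params)


class TestFit:
    def test_planted_recovery(self, rng):
        U0 = np.abs(rng.standard_normal((20, 4)))
        V0 = np.abs(rng.standard_normal((15, 4)))
        A = U0 @ V0.T
        params = SCMFParams(rank=4, theta=1e-8, sigma=0.0, max_sweeps=200)
        model = fit_scmf(A, np.zeros((20, 20)), np.zeros((15, 15)), params)
        rel = np.linalg.norm(model.U @ model.V.T - A) / np.linalg.norm(A)
        assert rel < 1e-3

    def test_objective_trace_non_increasing(self, rng):
        A = rng.random((8, 6))
        SM = rng.random((8, 8))
        SD = rng.random((6, 6))
        params = SCMFParams(rank=3, theta=2.0, sigma=1.0, max_sweeps=50, tol=0.0)
        model = fit_scmf(A, SM, SD, params)
        trace = model.objective_trace
        for a, b in zip(trace, trace[1:]):
            assert b <= a + 1e-9

    def test_large_sigma_collapses_rows(self, rng):
        A = rng.random((6, 5))
        params = SCMFParams(rank=2, theta=0.1, sigma=1e6, max_sweeps=30)
        model = fit_scmf(A, np.ones((6, 6)), np.ones((5, 5)), params)
        spread = np.max(np.linalg.norm(model.U - model.U.mean(axis=0), axis=1))
        assert spread < 1e-3

    def test_determinism(self, rng):
        A = rng.random((7, 5))
        SM = rng.random((7, 7))
        SD = rng.random((5, 5))
        params = SCMFParams(rank=3, theta=1.0, sigma=0.5, init_mode="seeded-random", seed=42)
        m1 = fit_scmf(A, SM, SD, params)
        m2 = fit_scmf(A, SM, SD, params)
        np.testing.assert_array_equal(m1.U, m2.U)
        np.testing.assert_array_equal(m1.V, m2.V)

    def test_rank_exceeds_dims_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_scmf(rng.random((3, 4)), np.eye(3), np.eye(4), SCMFParams(rank=5))


class TestPredict:
    def test_zero_factors(self):
        from mirlink.scmf import SCMFModel

        model = SCMFModel(np.zeros((3, 2)), np.zeros((4, 2)), [0.0], True, 1, SCMFParams(rank=2))
        np.testing.assert_array_equal(predict_scores(model).scores, np.zeros((3, 4)))

    def test_rank_one_ones(self):
        from mirlink.scmf import SCMFModel

        model = SCMFModel(np.ones((3, 1)), np.ones((4, 1)), [0.0], True, 1, SCMFParams(rank=1))
        np.testing.assert_array_equal(predict_scores(model).scores, np.ones((3, 4)))

    def test_planted_heldout_auc(self):
        from sklearn.metrics.pairwise import cosine_similarity

        rng = np.random.default_rng(12345)
        U0 = np.abs(rng.standard_normal((100, 3)))
        V0 = np.abs(rng.standard_normal((60, 3)))
        scores = U0 @ V0.T
        A_full = (scores > np.quantile(scores, 0.9)).astype(float)
        pos = np.argwhere(A_full == 1)
        held = pos[rng.choice(len(pos), size=len(pos) // 10, replace=False)]
        A_train = A_full.copy()
        A_train[held[:, 0], held[:, 1]] = 0.0
        params = SCMFParams(rank=3, theta=1.0, sigma=1.0, max_sweeps=100)
        model = fit_scmf(A_train, cosine_similarity(U0), cosine_similarity(V0), params)
        P = predict_scores(model).scores
        s = np.concatenate([P[held[:, 0], held[:, 1]], P[A_full == 0]])
        lab = np.concatenate([np.ones(len(held)), np.zeros(int((A_full == 0).sum()))])
        assert auc_rank(s, lab) > 0.95
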