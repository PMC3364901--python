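import numpy as np
import pytest

from mrsnmf import (
    FactorizationOptions,
    SpectrumTable,
    ValidationError,
    factorize,
    initialize,
    reconstruction_error,
    split_signs,
    update_als,
    update_alsobs,
    update_alspg,
    update_convex,
    update_euc,
)
from mrsnmf.initializations import InitState

from conftest import random_table


def _table(V):
    V = np.atleast_2d(np.asarray(V, dtype=float))
    return SpectrumTable(np.linspace(4.0, 0.5, V.shape[0]), V)


class TestReconstructionError:
    def test_exact_factorization_is_zero(self, rng):
        W, H = rng.random((5, 2)), rng.random((2, 4))
        assert reconstruction_error(W @ H, W, H) == 0.0

    def test_identity_against_zero_factors(self):
        assert reconstruction_error(np.eye(2), np.zeros((2, 2)), np.zeros((2, 2))) == 1.0

    def test_matches_elementwise_sum_oracle(self, rng):
        V, W, H = rng.normal(size=(5, 4)), rng.normal(size=(5, 2)), rng.normal(size=(2, 4))
        R = V - W @ H
        oracle = 0.5 * sum(R[i, j] ** 2 for i in range(5) for j in range(4))
        assert abs(reconstruction_error(V, W, H) - oracle) < 1e-12

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            reconstruction_error(np.eye(3), np.eye(2), np.eye(2))


class TestEuc:
    def test_exact_factorization_is_fixed_point_up_to_rescaling(self, rng):
        W = rng.random((6, 2)) + 0.1
        H = rng.random((2, 5)) + 0.1
        V = W @ H
        W2, H2 = update_euc(W, H, V)
        # the product (hence the objective) is preserved at the fixed point
        assert np.max(np.abs(W2 @ H2 - V)) < 1e-8
        assert np.allclose(W2.sum(axis=0), 1.0)

    def test_scalar_case_hand_evaluated(self):
        W2, H2 = update_euc(np.array([[1.0]]), np.array([[1.0]]), np.array([[2.0]]))
        assert W2[0, 0] == pytest.approx(1.0)
        assert H2[0, 0] == pytest.approx(2.0)
        assert reconstruction_error(np.array([[2.0]]), W2, H2) < 1e-20

    def test_monotone_descent_and_second_transcription(self, rng):
        """100 sequential updates never increase the error, and agree with a
        directly transcribed implementation of the multiplicative rules."""
        V = rng.random((6, 5))
        W = rng.random((6, 2)) + 0.01
        H = rng.random((2, 5)) + 0.01
        W_ref, H_ref = W.copy(), H.copy()
        errors = [reconstruction_error(V, W, H)]
        for _ in range(100):
            W, H = update_euc(W, H, V)
            errors.append(reconstruction_error(V, W, H))
            # independent transcription: numerators/denominators elementwise
            num = V @ H_ref.T
            den = W_ref @ H_ref @ H_ref.T + 1e-12
            W_ref = np.array([[W_ref[i, a] * num[i, a] / den[i, a]
                               for a in range(2)] for i in range(6)])
            scale = W_ref.sum(axis=0)
            W_ref = W_ref / scale
            H_ref = H_ref * scale[:, None]
            num = W_ref.T @ V
            den = W_ref.T @ W_ref @ H_ref + 1e-12
            H_ref = np.array([[H_ref[a, j] * num[a, j] / den[a, j]
                               for j in range(5)] for a in range(2)])
        assert np.all(np.diff(errors) <= 1e-9)
        assert np.max(np.abs(W - W_ref)) < 1e-8
        assert np.max(np.abs(H - H_ref)) < 1e-8

    def test_negative_input_rejected(self):
        with pytest.raises(ValidationError):
            update_euc(np.array([[1.0]]), np.array([[1.0]]), np.array([[-1.0]]))


class TestAls:
    def test_orthonormal_exact_case(self):
        V = np.eye(2)
        W, H = update_als(np.zeros((2, 2)), np.eye(2), V)
        assert np.allclose(W, np.eye(2))
        assert np.allclose(H, np.eye(2))

    def test_equals_least_squares_then_clip_oracle(self, rng):
        for _ in range(20):
            V = rng.random((7, 6))
            H = rng.random((3, 6)) + 0.05
            W = rng.random((7, 3))
            W2, H2 = update_als(W, H, V)
            W_oracle = np.maximum(np.linalg.lstsq(H.T, V.T, rcond=None)[0].T, 0.0)
            assert np.max(np.abs(W2 - W_oracle)) < 1e-10
            H_oracle = np.maximum(np.linalg.lstsq(W2, V, rcond=None)[0], 0.0)
            assert np.max(np.abs(H2 - H_oracle)) < 1e-10

    def test_rank_deficient_H_uses_pseudo_inverse(self, rng):
        V = rng.random((6, 5))
        row = rng.random(5) + 0.1
        H = np.vstack([row, row])  # duplicate rows: singular Gram matrix
        W2, _ = update_als(rng.random((6, 2)), H, V)
        W_oracle = np.maximum((np.linalg.pinv(H.T) @ V.T).T, 0.0)
        res = np.linalg.norm(V - W2 @ H)
        res_oracle = np.linalg.norm(V - W_oracle @ H)
        assert abs(res - res_oracle) < 1e-8


class TestAlspg:
    def test_stationary_point_is_fixed(self, rng):
        W = rng.random((5, 2)) + 0.1
        H = rng.random((2, 4)) + 0.1
        V = W @ H
        W2, H2, ok = update_alspg(W, H, V)
        assert ok
        assert np.max(np.abs(H2 - H)) < 1e-12
        assert np.max(np.abs(W2 - W)) < 1e-12

    def test_projection_zeroes_negative_candidates(self):
        """A gradient step whose candidate lands at -0.3 is projected to 0."""
        from mrsnmf.nmf_core import FactorizationOptions, _pg_step

        X = np.array([[0.3]])
        # linear objective with constant gradient 0.6: the unit step gives
        # the candidate 0.3 - 0.6 = -0.3 and always satisfies Armijo
        X2, ok = _pg_step(
            X,
            grad_fn=lambda X: np.array([[0.6]]),
            obj_fn=lambda X: 0.6 * float(X[0, 0]),
            options=FactorizationOptions(),
        )
        assert ok
        assert X2[0, 0] == 0.0

    def test_objective_non_increasing_per_sweep(self, rng):
        V = rng.random((8, 6))
        W = rng.random((8, 3))
        H = rng.random((3, 6))
        f = reconstruction_error(V, W, H)
        for _ in range(50):
            W, H, _ = update_alspg(W, H, V)
            f2 = reconstruction_error(V, W, H)
            assert f2 <= f + 1e-12
            f = f2

    def test_converges_to_als_objective(self, rng):
        """Iterated to tight tolerance from the same init, the projected
        gradient driver reaches the ALS optimum (both bounded below by the
        unconstrained LS residual)."""
        V = rng.random((8, 6))
        W0 = rng.random((8, 2)) + 0.05
        H0 = rng.random((2, 6)) + 0.05
        Wa, Ha = W0.copy(), H0.copy()
        for _ in range(500):
            Wa, Ha = update_als(Wa, Ha, V)
        Wp, Hp = W0.copy(), H0.copy()
        for _ in range(5000):
            Wp, Hp, _ = update_alspg(Wp, Hp, V)
        f_als = reconstruction_error(V, Wa, Ha)
        f_pg = reconstruction_error(V, Wp, Hp)
        # unconstrained LS residual is a lower bound for both
        W_ls = np.linalg.lstsq(Ha.T, V.T, rcond=None)[0].T
        f_lower = reconstruction_error(V, W_ls, Ha)
        assert f_lower <= f_als + 1e-9
        assert abs(f_als - f_pg) < 1e-6


class TestAlsobs:
    def test_no_pruning_equals_plain_als(self, rng):
        # construct V = W H exactly so the LS solutions are non-negative
        W = rng.random((6, 2)) + 0.1
        H = rng.random((2, 5)) + 0.1
        V = W @ H
        Wa, Ha = update_als(W, H, V)
        Wo, Ho = update_alsobs(W, H, V)
        assert np.array_equal(Wa, Wo)
        assert np.array_equal(Ha, Ho)

    def test_single_prune_equals_constrained_least_squares(self):
        """OBS single-coordinate pruning lands exactly on the LS optimum
        constrained to that coordinate being zero (the classic OBS
        exactness property), verified by a direct constrained solve."""
        rng = np.random.default_rng(5)
        found = 0
        for _ in range(200):
            V = rng.normal(size=(1, 6)) + 0.3
            H = rng.random((2, 6)) + 0.1
            w_ls = np.linalg.lstsq(H.T, V.T, rcond=None)[0].ravel()
            if (w_ls < 0).sum() != 1:
                continue
            q = int(np.argmin(w_ls))
            keep = 1 - q
            h = H[keep]
            w_keep = float(V[0] @ h / (h @ h))  # exact LS with coordinate q pinned at 0
            if w_keep <= 0:
                continue
            found += 1
            Wo, _ = update_alsobs(np.zeros((1, 2)), H, V)
            expected = np.zeros(2)
            expected[keep] = w_keep
            assert np.max(np.abs(Wo[0] - expected)) < 1e-10
        assert found >= 20

    def test_adjustment_beats_plain_clipping(self):
        """Across random instances, the OBS re-adjustment yields a
        reconstruction at least as good as plain clipping almost always."""
        rng = np.random.default_rng(77)
        wins = 0
        trials = 100
        for _ in range(trials):
            V = rng.random((6, 8))
            W = rng.random((6, 3))
            H = rng.normal(size=(3, 8))  # mixed-sign H forces pruning in the W step
            H = np.abs(H)
            W_ls = np.linalg.lstsq(H.T, V.T, rcond=None)[0].T
            W_clip = np.maximum(W_ls, 0.0)
            f_clip = reconstruction_error(V, W_clip, H)
            Wo, _ = update_alsobs(W, H, V)
            f_obs = reconstruction_error(V, Wo, H)
            if f_obs <= f_clip + 1e-12:
                wins += 1
        assert wins >= 95


class TestSplitSigns:
    def test_definition(self):
        pos, neg = split_signs(np.array([[1.0, -2.0], [0.0, 3.0]]))
        assert np.array_equal(pos, [[1, 0], [0, 3]])
        assert np.array_equal(neg, [[0, 2], [0, 0]])

    def test_reconstruction_identity(self, rng):
        M = rng.normal(size=(6, 4))
        pos, neg = split_signs(M)
        assert np.array_equal(pos - neg, M)
        assert pos.min() >= 0 and neg.min() >= 0


class TestConvex:
    def test_nonnegative_data_keeps_positivity(self, rng):
        V = rng.random((6, 8))
        A = rng.random((8, 2)) + 0.05
        H = rng.random((2, 8)) + 0.05
        for _ in range(20):
            A, H = update_convex(A, H, V)
        assert A.min() >= 0 and H.min() >= 0

    def test_recovers_orthogonal_cluster_centroids(self):
        """Two repeated orthogonal columns: converged sources correlate
        perfectly with the analytic centroids e1, e2."""
        V = np.column_stack([np.tile([[1.0], [0.0]], 5), np.tile([[0.0], [1.0]], 5)])
        C = np.zeros((10, 2))
        C[:5, 0] = 1.0
        C[5:, 1] = 1.0
        from mrsnmf.initializations import indicator_to_convex_init

        H, A = indicator_to_convex_init(C, [5, 5])
        for _ in range(500):
            A, H = update_convex(A, H, V)
        W = V @ A
        centroids = np.eye(2)
        for j in range(2):
            cos = np.abs(centroids.T @ W[:, j]) / np.linalg.norm(W[:, j])
            assert cos.max() > 1 - 1e-6

    def test_mixed_sign_closure(self, rng):
        V = rng.normal(size=(5, 9))
        A = rng.random((9, 3)) + 0.05
        H = rng.random((3, 9)) + 0.05
        A2, H2 = update_convex(A, H, V)
        assert A2.min() >= 0 and H2.min() >= 0
        # W = V A lies in the column space of V by construction
        W = V @ A2
        proj = V @ np.linalg.lstsq(V, W, rcond=None)[0]
        assert np.max(np.abs(proj - W)) < 1e-10


class TestFactorize:
    def test_convergence_contract(self, lte3_cohort):
        table = lte3_cohort.table
        init = initialize(table, 3, "kmeans", "convex", seed=0)
        res = factorize(table, 3, "convex", init)
        assert res.converged
        assert abs(res.error_trace[-1] - res.error_trace[-2]) < 1e-5

    def test_tolerance_zero_runs_to_cap(self, rng):
        table = random_table(rng, d=8, n=6, mixed_sign=False)
        init = initialize(table, 2, "random", "nonneg", seed=1)
        res = factorize(table, 2, "euc", init,
                        FactorizationOptions(tolerance=0.0, max_iterations=50))
        assert not res.converged
        assert res.iterations == 50

    def test_mixed_sign_input_flagged_for_euc(self, rng):
        table = random_table(rng, d=8, n=6, mixed_sign=True)
        init = initialize(table, 2, "random", "nonneg", seed=1)
        res = factorize(table, 2, "euc", init)
        assert res.nonnegative_transformed
        assert res.W.min() >= 0 and res.H.min() >= 0

    def test_k_equal_d_rejected(self, rng):
        table = random_table(rng, d=6, n=8, mixed_sign=False)
        init = InitState(W0=np.ones((6, 6)), H0=np.ones((6, 8)), A0=None,
                         strategy="random", method_family="nonneg", seed=0)
        with pytest.raises(ValidationError):
            factorize(table, 6, "euc", init)

    def test_family_mismatch_rejected(self, rng):
        table = random_table(rng, d=8, n=6)
        init = initialize(table, 2, "random", "nonneg", seed=1)
        with pytest.raises(ValidationError):
            factorize(table, 2, "convex", init)

    def test_determinism_given_init(self, rng):
        table = random_table(rng, d=10, n=8, mixed_sign=False)
        init = initialize(table, 2, "random", "nonneg", seed=9)
        a = factorize(table, 2, "als", init)
        b = factorize(table, 2, "als", init)
        assert np.array_equal(a.error_trace, b.error_trace)
        assert np.array_equal(a.W, b.W)

    def test_convex_maintains_column_space_constraint(self, lte3_cohort):
        table = lte3_cohort.table
        init = initialize(table, 3, "pca", "convex", seed=2)
        res = factorize(table, 3, "convex", init)
        assert np.linalg.norm(res.W - table.intensities @ res.A) < 1e-10
        assert res.A.min() >= 0 and res.H.min() >= 0
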