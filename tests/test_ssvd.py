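"""Dense and sparse SVD: oracles, planted instances, tuning, deflation."""

import numpy as np
import pytest

from omicsvd import PenaltySpec, decompose, deflate, dense_svd, rank1_ssvd, tune_degree
from omicsvd.simulation import planted_rank1
from omicsvd.ssvd import FlatTuningCurveWarning, default_degree_grid


def principal_angles(A, B):
    """Largest principal angle between the column spaces of A and B."""
    qa, _ = np.linalg.qr(A)
    qb, _ = np.linalg.qr(B)
    s = np.linalg.svd(qa.T @ qb, compute_uv=False)
    return float(np.arccos(np.clip(s.min(), -1, 1)))


class TestDenseSvd:
    def test_diagonal_matrix(self):
        f = dense_svd(np.diag([3.0, 1.0]), 1)
        assert f.d[0] == pytest.approx(3.0)
        np.testing.assert_allclose(np.abs(f.V[:, 0]), [1.0, 0.0], atol=1e-12)

    def test_matches_full_svd_oracle(self, rng):
        X = rng.standard_normal((20, 30))
        f = dense_svd(X, 5)
        U, s, Vt = np.linalg.svd(X)
        np.testing.assert_allclose(f.d, s[:5], rtol=1e-10)
        for k in range(5):
            np.testing.assert_allclose(np.abs(f.V[:, k]), np.abs(Vt[k]), atol=1e-8)

    def test_rank_deficient_tail(self, rng):
        A = rng.standard_normal((10, 2)) @ rng.standard_normal((2, 8))
        f = dense_svd(A, 3)
        assert f.d[2] == pytest.approx(0.0, abs=1e-10)

    def test_k_out_of_range(self, rng):
        with pytest.raises(ValueError):
            dense_svd(rng.standard_normal((4, 6)), 5)

    def test_sign_convention(self, rng):
        f = dense_svd(rng.standard_normal((15, 10)), 3)
        for k in range(3):
            assert f.V[np.argmax(np.abs(f.V[:, k])), k] > 0


class TestRank1Ssvd:
    def test_zero_penalty_reproduces_leading_triplet(self, rng):
        X = rng.standard_normal((25, 40))
        res = rank1_ssvd(X, PenaltySpec(alpha=1.0, lam=0.0))
        U, s, Vt = np.linalg.svd(X)
        assert res.d == pytest.approx(s[0], rel=1e-10)
        np.testing.assert_allclose(np.abs(res.v), np.abs(Vt[0]), atol=1e-8)
        assert res.converged

    def test_planted_noiseless_support(self, rng):
        u0 = rng.standard_normal(30)
        u0 /= np.linalg.norm(u0)
        v0 = np.zeros(50)
        idx = rng.choice(50, 5, replace=False)
        v0[idx] = rng.uniform(1, 2, 5)
        v0 /= np.linalg.norm(v0)
        X = 7.5 * np.outer(u0, v0)
        res = rank1_ssvd(X, PenaltySpec(alpha=1.0, degree=5))
        assert set(np.flatnonzero(res.v)) == set(idx)
        assert res.d == pytest.approx(7.5, abs=1e-6)

    def test_positive_outer_product_converges_fast(self):
        X = np.outer([1.0, 2.0, 3.0], [4.0, 5.0, 6.0, 7.0])
        res = rank1_ssvd(X, PenaltySpec(alpha=1.0, degree=4))
        assert res.converged and res.n_iter <= 2
        assert np.all(res.v > 0)

    def test_unit_norms_and_exact_degree(self, rng):
        X = rng.standard_normal((40, 60))
        res = rank1_ssvd(X, PenaltySpec(alpha=0.8, degree=12))
        assert np.linalg.norm(res.u) == pytest.approx(1.0)
        assert np.linalg.norm(res.v) == pytest.approx(1.0)
        assert np.count_nonzero(res.v) == 12

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            rank1_ssvd(np.zeros((5, 5)), PenaltySpec(alpha=1.0, lam=0.0))

    def test_objective_monotone_in_debug_mode(self, rng):
        for seed in range(5):
            X = np.random.default_rng(seed).standard_normal((30, 50))
            res = rank1_ssvd(
                X, PenaltySpec(alpha=0.7, lam=2.0), track_objective=True
            )
            hist = np.array(res.objective_history)
            assert hist.size >= 1
            assert np.all(np.diff(hist) <= 1e-8)


class TestDeflate:
    def test_rank1_self_deflation_is_zero(self, rng):
        u = rng.standard_normal(8)
        u /= np.linalg.norm(u)
        v = rng.standard_normal(6)
        v /= np.linalg.norm(v)
        X = 4.2 * np.outer(u, v)
        np.testing.assert_allclose(deflate(X, u, 4.2, v), 0.0, atol=1e-10)

    def test_residual_spectrum_shifts(self, rng):
        # after deflating k dense factors the residual's top singular value
        # is the (k+1)-th of the original
        X = rng.standard_normal((15, 12))
        s = np.linalg.svd(X, compute_uv=False)
        R = X.copy()
        for k in range(3):
            f = dense_svd(R, 1)
            R = deflate(R, f.U[:, 0], f.d[0], f.V[:, 0])
            top = np.linalg.svd(R, compute_uv=False)[0]
            assert top == pytest.approx(s[k + 1], rel=1e-8)

    def test_zero_singular_value_is_identity(self, rng):
        X = rng.standard_normal((5, 4))
        np.testing.assert_array_equal(deflate(X, np.ones(5), 0.0, np.ones(4)), X)


class TestTuneDegree:
    def test_planted_signal_selects_true_degree(self):
        hits = []
        for seed in range(20):
            X, _ = planted_rank1(100, 50, 10, d0=5 * np.sqrt(100), seed=seed)
            t = tune_degree(X, 1.0, range(2, 31))
            hits.append(int(t.selected_degree[0]))
        # modal choice across replicates is the planted degree
        assert max(set(hits), key=hits.count) == 10

    def test_pure_noise_warns_flat_curve(self):
        X = np.random.default_rng(0).standard_normal((100, 50))
        with pytest.warns(FlatTuningCurveWarning):
            t = tune_degree(X, 1.0, range(2, 31))
        assert t.selected_degree[0] in range(2, 31)

    def test_single_candidate_grid(self, rng):
        X = rng.standard_normal((20, 10))
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FlatTuningCurveWarning)
            t = tune_degree(X, 1.0, [10])
        assert t.selected_degree[0] == 10
        assert t.criterion_values.shape == (1, 1)

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            tune_degree(rng.standard_normal((10, 5)), 1.0, [])

    def test_selected_minimizes_criterion(self):
        X, _ = planted_rank1(80, 40, 8, d0=5 * np.sqrt(80), seed=3)
        t = tune_degree(X, 1.0, range(2, 25))
        j = list(t.candidate_degrees).index(t.selected_degree[0])
        assert t.criterion_values[0, j] == t.criterion_values[0].min()


class TestDecompose:
    def test_zero_penalty_matches_dense_svd(self, rng):
        X = rng.standard_normal((30, 45))
        f, tuning = decompose(X, 4, penalty=PenaltySpec(alpha=1.0, lam=0.0))
        ref = dense_svd(X, 4)
        assert tuning is None
        np.testing.assert_allclose(f.d, ref.d, rtol=1e-8)
        np.testing.assert_allclose(np.abs(f.V), np.abs(ref.V), atol=1e-6)

    def test_disjoint_planted_supports_recovered(self, rng):
        n, p = 60, 80
        u1, u2 = np.linalg.qr(rng.standard_normal((n, 2)))[0].T
        v1 = np.zeros(p)
        v1[:6] = 1 / np.sqrt(6)
        v2 = np.zeros(p)
        v2[40:48] = 1 / np.sqrt(8)
        X = 60 * np.outer(u1, v1) + 35 * np.outer(u2, v2) + 0.1 * rng.standard_normal((n, p))
        f, _ = decompose(X, 2, penalty="auto", candidate_degrees=range(2, 21))
        supports = [set(np.flatnonzero(f.V[:, k])) for k in range(2)]
        assert supports[0] == set(range(6))
        assert supports[1] == set(range(40, 48))

    def test_symmetric_positive_matrix_nonnegative_factor(self):
        X = np.full((6, 6), 1.0) + np.diag(np.ones(6))
        f, _ = decompose(X, 1, penalty=PenaltySpec(alpha=1.0, lam=0.0))
        assert np.all(f.V[:, 0] >= -1e-12) and np.all(f.U[:, 0] >= -1e-12)

    def test_scale_equivariance(self, rng):
        X = rng.standard_normal((25, 30))
        f1, _ = decompose(X, 3, penalty=PenaltySpec(alpha=1.0, lam=0.0))
        f2, _ = decompose(5.0 * X, 3, penalty=PenaltySpec(alpha=1.0, lam=0.0))
        np.testing.assert_allclose(f2.d, 5.0 * f1.d, rtol=1e-8)
        np.testing.assert_allclose(f2.V, f1.V, atol=1e-7)
        np.testing.assert_allclose(f2.U, f1.U, atol=1e-7)

    def test_dense_initializations_attached(self, rng):
        X = rng.standard_normal((20, 25))
        f, _ = decompose(X, 2, penalty=PenaltySpec(alpha=1.0, degree=5))
        assert f.dense is not None
        assert f.dense.d[0] == pytest.approx(np.linalg.svd(X, compute_uv=False)[0], rel=1e-8)
        assert list(f.nnz) == [5, 5]

    def test_auto_returns_tuning_grid(self):
        X, _ = planted_rank1(60, 40, 6, d0=5 * np.sqrt(60), seed=1)
        f, tuning = decompose(X, 1, penalty="auto", candidate_degrees=range(2, 21))
        assert tuning is not None
        assert tuning.selected_degree[0] == f.nnz[0]

    def test_default_grid_is_log_spaced_from_1_to_p(self):
        grid = default_degree_grid(500)
        assert grid[0] == 1 and grid[-1] == 500 and len(grid) <= 20
        assert np.all(np.diff(grid) > 0)

    def test_singular_values_descending(self, rng):
        X = rng.standard_normal((30, 40))
        f, _ = decompose(X, 4, penalty=PenaltySpec(alpha=1.0, degree=10))
        assert np.all(np.diff(f.d) <= 0)
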