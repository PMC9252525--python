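import numpy as np
import pytest

from bnmscca.exceptions import DegenerateWeightError, NumericalError, ValidationError
from bnmscca.solvers import (
    BNMSCCA,
    MSCCA,
    SCCA,
    SCCAR,
    HyperParams,
    build_reweight_diagonals,
    ccc,
    group_norm,
    objective_bnmscca,
    scale_to_unit,
    soft_threshold,
    update_u,
    update_v,
    update_w,
)
from bnmscca.synthetic import generate_groups, generate_multiview


def _standardized(A):
    return (A - A.mean(axis=0)) / A.std(axis=0)


class TestPrimitives:
    def test_soft_threshold_values(self):
        assert soft_threshold(1.5, 1.0) == pytest.approx(0.5)
        assert soft_threshold(-0.3, 1.0) == pytest.approx(0.0)
        np.testing.assert_allclose(
            soft_threshold([-2.0, 0.5, 2.0], 1.0), [-1.0, 0.0, 1.0]
        )

    def test_scale_to_unit(self, rng):
        np.testing.assert_allclose(
            scale_to_unit(np.eye(2), [3.0, 4.0]), [0.6, 0.8]
        )
        a = np.array([0.6, 0.8])  # already unit under identity
        np.testing.assert_allclose(scale_to_unit(np.eye(2), a * 1.0), a)
        M = rng.standard_normal((9, 4))
        out = scale_to_unit(M, rng.standard_normal(4))
        assert np.linalg.norm(M @ out) == pytest.approx(1.0, abs=1e-12)
        with pytest.raises(DegenerateWeightError):
            scale_to_unit(np.zeros((3, 2)), [1.0, 1.0])

    def test_ccc_identity_and_sign(self, rng):
        X = rng.standard_normal((40, 5))
        u = rng.standard_normal(5)
        assert ccc(X, X, u, u) == pytest.approx(1.0)
        assert ccc(X, X, u, -u) == pytest.approx(-1.0)

    def test_ccc_null_is_small(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((1000, 4))
        Y = rng.standard_normal((1000, 4))
        assert abs(ccc(X, Y, rng.standard_normal(4), rng.standard_normal(4))) < 0.1

    def test_ccc_zero_variance_rejected(self):
        X = np.random.default_rng(0).standard_normal((10, 2))
        with pytest.raises(NumericalError):
            ccc(X, X, np.zeros(2), np.ones(2))


class TestDiagonals:
    def test_entries_match_formulas_in_eps_limit(self):
        d = build_reweight_diagonals(
            [1.0, -2.0], [1.0, 1.0], [1.0], epsilon=1e-15
        )
        np.testing.assert_allclose(d.d1, [1.0, 0.5])
        # one network holding (3, 4): |U| = 5, printed entry 1/(2*5)
        g = generate_groups(2, 1)
        d = build_reweight_diagonals(
            [3.0, 4.0], [3.0, 4.0], [1.0], groups=g, epsilon=1e-15
        )
        np.testing.assert_allclose(d.dbar1, [0.1, 0.1])
        # majorization-consistent variant drops the factor 2
        d = build_reweight_diagonals(
            [3.0, 4.0], [3.0, 4.0], [1.0], groups=g, epsilon=1e-15, variant="mm"
        )
        np.testing.assert_allclose(d.dbar1, [0.2, 0.2])

    def test_zero_entry_guarded_by_epsilon(self):
        d = build_reweight_diagonals([0.0, 1.0], [1.0], [0.0], epsilon=1e-6)
        assert d.d1[0] == pytest.approx(1e6)
        assert np.isfinite(d.d3).all()


class TestObjective:
    def test_zero_weights_give_zero(self, rng, small_groups):
        X = rng.standard_normal((8, 20))
        Y = rng.standard_normal((8, 20))
        Z = rng.standard_normal((8, 1))
        val = objective_bnmscca(
            X, Y, Z, np.zeros(20), np.zeros(20), np.zeros(1), small_groups
        )
        assert val == 0.0

    def test_penalty_free_reduction(self, rng):
        X = rng.standard_normal((10, 4))
        Y = rng.standard_normal((10, 3))
        Z = rng.standard_normal((10, 1))
        u = scale_to_unit(X, rng.standard_normal(4))
        v = scale_to_unit(Y, rng.standard_normal(3))
        w = scale_to_unit(Z, rng.standard_normal(1))
        hp = HyperParams(0.0, 0.0, 0.0, 0.0, 0.0)
        bilinear = (X @ u) @ (Y @ v) + (Y @ v) @ (Z @ w) + (Z @ w) @ (X @ u)
        assert objective_bnmscca(X, Y, Z, u, v, w, hp=hp) == pytest.approx(
            1.5 - bilinear, abs=1e-12
        )

    def test_matches_naive_termwise_oracle(self, rng):
        n, p, q, r = 8, 4, 3, 1
        X = rng.standard_normal((n, p))
        Y = rng.standard_normal((n, q))
        Z = rng.standard_normal((n, r))
        u, v, w = rng.standard_normal(p), rng.standard_normal(q), rng.standard_normal(r)
        gx, gy = generate_groups(p, 2), generate_groups(q, 2)
        hp = HyperParams(0.7, 1.3, 0.2, 0.4, 0.6)
        # independent naive summation of every term
        Xu, Yv, Zw = X @ u, Y @ v, Z @ w
        want = (
            -sum(Xu[i] * Yv[i] for i in range(n))
            - sum(Yv[i] * Zw[i] for i in range(n))
            - sum(Zw[i] * Xu[i] for i in range(n))
            + 0.5 * sum(x * x for x in Xu)
            + 0.5 * sum(x * x for x in Yv)
            + 0.5 * sum(x * x for x in Zw)
            + 0.7 * 0.4 * group_norm(u, gx.index_blocks)
            + 0.7 * 0.6 * sum(abs(x) for x in u)
            + 1.3 * 0.6 * group_norm(v, gy.index_blocks)
            + 1.3 * 0.4 * sum(abs(x) for x in v)
            + 0.2 * sum(abs(x) for x in w)
        )
        got = objective_bnmscca(X, Y, Z, u, v, w, gx, gy, hp)
        assert got == pytest.approx(want, abs=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        X = rng.standard_normal((5, 3))
        with pytest.raises(ValidationError):
            objective_bnmscca(X, X, X[:, :1], np.ones(4), np.ones(3), np.ones(1))


class TestBlockUpdates:
    def test_zero_rhs_gives_zero(self, rng):
        X = rng.standard_normal((10, 4))
        Y = rng.standard_normal((10, 3))
        Z = rng.standard_normal((10, 1))
        hp = HyperParams(0.5, 0.5, 0.5)
        d = build_reweight_diagonals(np.ones(4), np.ones(3), np.ones(1))
        u = update_u(X, Y, Z, np.zeros(3), np.zeros(1), d, hp)
        np.testing.assert_allclose(u, 0.0, atol=1e-14)

    def test_two_by_two_closed_form(self):
        # diagonal X'X with hand-set penalties: system is diagonal, solve by hand
        X = np.array([[1.0, 0.0], [0.0, 2.0], [0.0, 0.0]])
        Y = np.array([[1.0], [1.0], [0.0]])
        Z = np.array([[0.0], [1.0], [1.0]])
        v, w = np.array([1.0]), np.array([1.0])
        hp = HyperParams(2.0, 1.0, 1.0, alpha=0.0, epsilon=1e-15)
        d = build_reweight_diagonals(np.array([1.0, 1.0]), v, w, epsilon=1e-15)
        # A = diag(1,4) + 2*diag(1,1); rhs = X'(Yv+Zw) = (1, 4)
        want = np.array([1.0 / 3.0, 4.0 / 6.0])
        got = update_u(X, Y, Z, v, w, d, hp)
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_linear_system_residuals(self, rng):
        n, p, q, r = 30, 6, 5, 1
        X = rng.standard_normal((n, p))
        Y = rng.standard_normal((n, q))
        Z = rng.standard_normal((n, r))
        gx, gy = generate_groups(p, 2), generate_groups(q, 2)
        u0, v0, w0 = rng.standard_normal(p), rng.standard_normal(q), rng.standard_normal(r)
        hp = HyperParams(0.8, 1.1, 0.3, 0.5, 0.5)
        d = build_reweight_diagonals(u0, v0, w0, gx, gy)
        u = update_u(X, Y, Z, v0, w0, d, hp)
        A = X.T @ X + hp.lambda1 * hp.alpha * np.diag(d.dbar1) \
            + hp.lambda1 * (1 - hp.alpha) * np.diag(d.d1)
        assert np.linalg.norm(A @ u - X.T @ (Y @ v0 + Z @ w0)) < 1e-8
        v = update_v(X, Y, Z, u0, w0, d, hp)
        B = Y.T @ Y + hp.lambda2 * hp.beta * np.diag(d.dbar2) \
            + hp.lambda2 * (1 - hp.beta) * np.diag(d.d2)
        assert np.linalg.norm(B @ v - Y.T @ (X @ u0 + Z @ w0)) < 1e-8
        w = update_w(X, Y, Z, u0, v0, d, hp)
        C = Z.T @ Z + hp.lambda3 * np.diag(d.d3)
        assert np.linalg.norm(C @ w - Z.T @ (X @ u0 + Y @ v0)) < 1e-8


class TestBNMSCCA:
    def test_unit_constraints_after_fit(self, small_data, small_groups):
        est = BNMSCCA(1, 1, 1, groups=small_groups).fit(
            small_data.X, small_data.Y, small_data.Z
        )
        Xs = _standardized(small_data.X)
        Ys = _standardized(small_data.Y)
        Zs = _standardized(small_data.Z.reshape(-1, 1))
        assert np.linalg.norm(Xs @ est.u_) == pytest.approx(1.0, abs=1e-8)
        assert np.linalg.norm(Ys @ est.v_) == pytest.approx(1.0, abs=1e-8)
        assert np.linalg.norm(Zs @ est.w_) == pytest.approx(1.0, abs=1e-8)

    def test_support_concentrates_on_active_network(self, small_groups):
        data = generate_multiview(
            200, 20, 20, small_groups, latent_corr=0.6, seed=5, K=4, n_active=1
        )
        est = BNMSCCA(10, 10, 10, groups=small_groups).fit(data.X, data.Y, data.Z)
        mass = np.abs(est.u_)[data.true_u != 0].sum() / np.abs(est.u_).sum()
        assert mass >= 0.8

    def test_shrinkage_with_lambda(self, small_groups):
        noise = generate_multiview(
            100, 20, 20, small_groups, latent_corr=0.0, seed=2, K=4
        )
        big = BNMSCCA(100, 100, 100, groups=small_groups).fit(
            noise.X, noise.Y, noise.Z
        )
        small = BNMSCCA(0.01, 0.01, 0.01, groups=small_groups).fit(
            noise.X, noise.Y, noise.Z
        )
        assert np.abs(big.u_).sum() < np.abs(small.u_).sum()
        assert np.abs(big.v_).sum() < np.abs(small.v_).sum()

    def test_deterministic_repeat_bitwise(self, small_data, small_groups):
        kw = dict(groups=small_groups, init="random", random_state=7)
        a = BNMSCCA(1, 1, 1, **kw).fit(small_data.X, small_data.Y, small_data.Z)
        b = BNMSCCA(1, 1, 1, **kw).fit(small_data.X, small_data.Y, small_data.Z)
        assert a.objective_trace_ == b.objective_trace_
        np.testing.assert_array_equal(a.u_, b.u_)

    def test_sign_convention(self, small_data, small_groups):
        est = BNMSCCA(1, 1, 1, groups=small_groups).fit(
            small_data.X, small_data.Y, small_data.Z
        )
        assert est.u_[np.argmax(np.abs(est.u_))] > 0

    def test_objective_trace_non_increasing(self, small_data, small_groups):
        # exact block minimization on the constraint set with the
        # majorization-consistent diagonals: provably monotone descent
        est = BNMSCCA(
            1, 1, 1, groups=small_groups, variant="mm", constraint="constrained"
        ).fit(small_data.X, small_data.Y, small_data.Z)
        tr = np.asarray(est.objective_trace_)
        assert (np.diff(tr) <= 1e-6 * np.abs(tr[:-1])).all()

    def test_constrained_mode_keeps_exact_unit_norms(self, small_data, small_groups):
        est = BNMSCCA(
            1, 1, 1, groups=small_groups, variant="mm", constraint="constrained"
        ).fit(small_data.X, small_data.Y, small_data.Z)
        Xs = _standardized(small_data.X)
        assert np.linalg.norm(Xs @ est.u_) == pytest.approx(1.0, abs=1e-10)

    def test_alpha_zero_requires_no_groups(self, small_data):
        est = BNMSCCA(1, 1, 1, alpha=0.0, beta=0.0).fit(
            small_data.X, small_data.Y, small_data.Z
        )
        assert est.converged_

    def test_alpha_positive_without_groups_rejected(self, small_data):
        with pytest.raises(ValidationError, match="group structure"):
            BNMSCCA(1, 1, 1, alpha=0.5).fit(
                small_data.X, small_data.Y, small_data.Z
            )

    def test_transform_and_score_roundtrip(self, small_data, small_groups):
        est = BNMSCCA(1, 1, 1, groups=small_groups).fit(
            small_data.X, small_data.Y, small_data.Z
        )
        s, t = est.transform(small_data.X, small_data.Y)
        assert est.score(small_data.X, small_data.Y) == pytest.approx(
            np.corrcoef(s, t)[0, 1]
        )

    def test_sklearn_clone_compatible(self, small_groups):
        from sklearn.base import clone

        est = BNMSCCA(2, 3, 4, alpha=0.25, groups=small_groups)
        c = clone(est)
        assert c.get_params()["lambda2"] == 3 and c.get_params()["alpha"] == 0.25


class TestMSCCA:
    def test_equals_bnmscca_with_zero_mixing(self, small_data):
        a = BNMSCCA(1, 1, 1, alpha=0.0, beta=0.0).fit(
            small_data.X, small_data.Y, small_data.Z
        )
        b = MSCCA(1, 1, 1).fit(small_data.X, small_data.Y, small_data.Z)
        np.testing.assert_allclose(a.u_, b.u_, atol=1e-8)
        np.testing.assert_allclose(a.v_, b.v_, atol=1e-8)
        np.testing.assert_allclose(a.w_, b.w_, atol=1e-8)

    def test_large_lambda_sparser(self, small_groups):
        noise = generate_multiview(
            100, 20, 20, small_groups, latent_corr=0.0, seed=4, K=4
        )
        big = MSCCA(100, 100, 100).fit(noise.X, noise.Y, noise.Z)
        small = MSCCA(0.01, 0.01, 0.01).fit(noise.X, noise.Y, noise.Z)
        assert (np.abs(big.u_) > 1e-6).sum() <= (np.abs(small.u_) > 1e-6).sum()


class TestSCCA:
    def test_self_association(self, rng):
        X = rng.standard_normal((100, 8))
        est = SCCA(0.01, 0.01).fit(X, X.copy())
        assert est.correlation_ == pytest.approx(1.0, abs=1e-3)

    def test_rank_one_recovers_singular_vectors(self):
        rng = np.random.default_rng(3)
        ut = np.zeros(10); ut[:3] = [2.0, 1.0, -1.0]
        vt = np.zeros(8); vt[4:] = [1.0, 2.0, 1.0, 0.5]
        s = rng.standard_normal(500)
        X = np.outer(s, ut) + 0.01 * rng.standard_normal((500, 10))
        Y = np.outer(s, vt) + 0.01 * rng.standard_normal((500, 8))
        est = SCCA(0.05, 0.05).fit(X, Y)
        Xs, Ys = _standardized(X), _standardized(Y)
        U, _, Vt = np.linalg.svd(Xs.T @ Ys)
        assert abs(est.u_ @ U[:, 0]) / np.linalg.norm(est.u_) >= 0.99
        assert abs(est.v_ @ Vt[0]) / np.linalg.norm(est.v_) >= 0.99

    def test_larger_c_is_sparser(self, rng):
        X = rng.standard_normal((80, 12))
        Y = rng.standard_normal((80, 12))
        loose = SCCA(0.05, 0.05).fit(X, Y)
        tight = SCCA(0.46, 0.46).fit(X, Y)
        assert (np.abs(tight.u_) > 1e-10).sum() <= (np.abs(loose.u_) > 1e-10).sum()

    def test_budget_infeasible_warns_and_keeps_one(self, rng):
        X = rng.standard_normal((50, 6))
        Y = rng.standard_normal((50, 5))
        with pytest.warns(UserWarning, match="infeasible"):
            est = SCCA(1.0, 1.0).fit(X, Y)
        assert (np.abs(est.u_) > 0).sum() == 1

    def test_invalid_budget_rejected(self, rng):
        with pytest.raises(ValidationError):
            SCCA(0.0, 0.5).fit(np.ones((5, 2)), np.ones((5, 2)))


class TestSCCAR:
    def test_gamma_zero_reduces_to_scca(self, rng):
        X = rng.standard_normal((100, 9))
        Y = rng.standard_normal((100, 7))
        z = rng.integers(0, 2, 100).astype(float)
        a = SCCA(0.2, 0.2).fit(X, Y)
        b = SCCAR(0.2, 0.2, gamma=0.0).fit(X, Y, z)
        np.testing.assert_array_equal(a.u_, b.u_)
        np.testing.assert_array_equal(a.v_, b.v_)

    def test_diagnosis_pull_promotes_aligned_column(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((200, 10))
        Y = rng.standard_normal((200, 6))
        z = X[:, 7] + 0.1 * rng.standard_normal(200)
        rank = lambda est: np.argsort(-np.abs(est.u_)).tolist().index(7)
        r0 = rank(SCCAR(0.2, 0.2, gamma=0.0).fit(X, Y, z))
        r5 = rank(SCCAR(0.2, 0.2, gamma=5.0).fit(X, Y, z))
        assert r5 < r0

    def test_deterministic_repeat(self, rng):
        X = rng.standard_normal((60, 5))
        Y = rng.standard_normal((60, 4))
        z = rng.integers(0, 2, 60).astype(float)
        a = SCCAR(0.3, 0.3, gamma=1.0).fit(X, Y, z)
        b = SCCAR(0.3, 0.3, gamma=1.0).fit(X, Y, z)
        np.testing.assert_array_equal(a.u_, b.u_)
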