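import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mota.blocks import GroupedStudy, OmicBlock
from mota.intra import (
    call_intra_edges,
    delta_pc,
    graphical_lasso,
    partial_corr,
    permutation_null,
    select_rho,
    standardize,
    support_size,
)
from mota.synthetic import random_sparse_precision


def residual_partial_corr(X: np.ndarray) -> np.ndarray:
    """Brute-force partial correlation: correlate the residuals of each pair
    after regressing both variables on all the remaining ones."""
    n, h = X.shape
    out = np.zeros((h, h))
    for i in range(h):
        for j in range(i + 1, h):
            others = [k for k in range(h) if k not in (i, j)]
            A = np.column_stack([X[:, others], np.ones(n)])
            ri = X[:, i] - A @ np.linalg.lstsq(A, X[:, i], rcond=None)[0]
            rj = X[:, j] - A @ np.linalg.lstsq(A, X[:, j], rcond=None)[0]
            out[i, j] = out[j, i] = np.corrcoef(ri, rj)[0, 1]
    return out


class TestStandardize:
    def test_moments(self):
        Z = standardize(np.array([[1.0], [2.0], [3.0]]))
        assert abs(Z.mean()) < 1e-12
        assert Z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        Z = standardize(rng.standard_normal((50, 4)))
        np.testing.assert_allclose(standardize(Z), Z, atol=1e-12)

    def test_constant_column_named_in_error(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 2.0)])
        with pytest.raises(ValueError, match="flat"):
            standardize(X, feature_ids=["ok", "flat"])


class TestGraphicalLasso:
    def test_rho_zero_is_plain_inverse(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((500, 3))
        S = np.cov(X, rowvar=False)
        theta, _ = graphical_lasso(S, 0.0)
        np.testing.assert_allclose(theta, np.linalg.inv(S), atol=1e-6)

    def test_huge_rho_kills_all_offdiagonals(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((100, 4))
        S = np.cov(standardize(X), rowvar=False)
        rho = np.abs(S - np.diag(np.diag(S))).max() * 1.01
        theta, _ = graphical_lasso(S, rho)
        off = theta - np.diag(np.diag(theta))
        assert np.abs(off).max() < 1e-10

    def test_kkt_optimality(self):
        # independent optimality check of the solver output: at the optimum
        # of log det(T) - tr(S T) - rho*||T||_1,offdiag, W = T^{-1} satisfies
        # W_ij = S_ij + rho*sign(T_ij) on the support, |W_ij - S_ij| <= rho
        # off the support, and W_ii = S_ii.
        rng = np.random.default_rng(3)
        X = rng.standard_normal((60, 5))
        S = np.cov(standardize(X), rowvar=False)
        rho = 0.1
        theta, obj = graphical_lasso(S, rho, tol=1e-6, max_iter=2000)
        W = np.linalg.inv(theta)
        assert np.isfinite(obj)
        h = S.shape[0]
        for i in range(h):
            assert W[i, i] == pytest.approx(S[i, i], abs=1e-4)
            for j in range(i + 1, h):
                if abs(theta[i, j]) > 1e-10:
                    assert W[i, j] - S[i, j] == pytest.approx(
                        rho * np.sign(theta[i, j]), abs=1e-4)
                else:
                    assert abs(W[i, j] - S[i, j]) <= rho + 1e-4

    def test_support_monotone_in_rho(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((80, 8)) @ rng.standard_normal((8, 8))
        S = np.cov(standardize(X), rowvar=False)
        sizes = [support_size(graphical_lasso(S, rho)[0])
                 for rho in [0.05, 0.1, 0.2, 0.4, 0.8]]
        assert sizes == sorted(sizes, reverse=True)

    def test_asymmetric_covariance_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            graphical_lasso(np.array([[1.0, 0.5], [0.2, 1.0]]), 0.1)


class TestSelectRho:
    def test_single_grid_value_returned(self):
        rng = np.random.default_rng(5)
        X = standardize(rng.standard_normal((40, 5)))
        rho, _ = select_rho(X, grid=np.array([0.3]))
        assert rho == 0.3

    def test_one_se_rule_at_least_cv_minimizer(self):
        # simulated sparse precision: the one-SE rho is >= the CV minimizer,
        # hence the selected model is at least as sparse
        theta = random_sparse_precision(10, 6)
        rng = np.random.default_rng(7)
        X = rng.multivariate_normal(np.zeros(10), np.linalg.inv(theta), size=200)
        X = standardize(X)
        rho, info = select_rho(X, folds=5)
        assert rho >= info["rho_min_cv"]
        S = np.cov(X, rowvar=False)
        assert (support_size(graphical_lasso(S, rho)[0])
                <= support_size(graphical_lasso(S, info["rho_min_cv"])[0]))


class TestPartialCorr:
    def test_identity_gives_zero(self):
        np.testing.assert_array_equal(partial_corr(np.eye(3)), np.zeros((3, 3)))

    def test_hand_example(self):
        # pc_12 = -theta_12 / sqrt(theta_11 theta_22) = 1/2
        pc = partial_corr(np.array([[2.0, -1.0], [-1.0, 2.0]]))
        assert pc[0, 1] == pytest.approx(0.5)

    def test_matches_residual_regression(self):
        rng = np.random.default_rng(8)
        X = rng.multivariate_normal(
            np.zeros(4),
            np.linalg.inv(random_sparse_precision(4, 9, density=0.5)),
            size=600,
        )
        theta = np.linalg.inv(np.cov(X, rowvar=False))
        np.testing.assert_allclose(
            partial_corr(theta), residual_partial_corr(X), atol=1e-8
        )

    def test_nonpositive_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            partial_corr(np.array([[1.0, 0.0], [0.0, -1.0]]))


class TestDeltaPc:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_antisymmetric(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.uniform(-1, 1, (2, 4, 4))
        np.testing.assert_array_equal(delta_pc(a, b), -delta_pc(b, a))

    def test_arithmetic(self):
        a = np.array([[0.0, 0.8], [0.8, 0.0]])
        b = np.array([[0.0, 0.1], [0.1, 0.0]])
        assert delta_pc(a, b)[0, 1] == pytest.approx(0.7)


def _null_study(seed=0, n=20, h=5):
    rng = np.random.default_rng(seed)
    samples = [f"s{i}" for i in range(2 * n)]
    block = OmicBlock("m", samples, [f"f{i}" for i in range(h)],
                      rng.standard_normal((2 * n, h)))
    groups = {s: (1 if i < n else 2) for i, s in enumerate(samples)}
    return GroupedStudy(blocks=[block], group_of=groups)


class TestPermutationNull:
    def test_deterministic_under_seed(self):
        study = _null_study()
        a = permutation_null(study, 0.2, 0.2, n_perm=100, seed=5)
        b = permutation_null(study, 0.2, 0.2, n_perm=100, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_expected_length(self):
        study = _null_study(h=5)
        null = permutation_null(study, 0.2, 0.2, n_perm=100, seed=5)
        assert null.shape == (100 * 5 * 4 // 2,)

    def test_too_few_permutations_refused(self):
        with pytest.raises(ValueError, match="n_perm"):
            permutation_null(_null_study(), 0.2, 0.2, n_perm=10, seed=1)

    def test_seed_required(self):
        with pytest.raises(ValueError, match="seed"):
            permutation_null(_null_study(), 0.2, 0.2, n_perm=100)


class TestCallIntraEdges:
    def test_no_edges_when_delta_zero(self):
        delta = np.zeros((3, 3))
        null = np.concatenate([-np.linspace(0.1, 1, 50), np.linspace(0.1, 1, 50)])
        edges, lo, hi = call_intra_edges(delta, null)
        assert edges == set() and lo < 0 < hi

    def test_extreme_pair_called(self):
        delta = np.zeros((3, 3))
        delta[0, 2] = delta[2, 0] = 5.0
        null = np.random.default_rng(0).normal(0, 0.1, 1000)
        edges, _, _ = call_intra_edges(delta, null)
        assert edges == {(0, 2)}

    def test_tail_bounds_checked(self):
        with pytest.raises(ValueError, match="tail"):
            call_intra_edges(np.zeros((2, 2)), np.ones(100), tail=0.6)
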