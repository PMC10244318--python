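import numpy as np
import pytest

import finecomp as fc
from finecomp.errors import DegenerateMatrixError, DegenerateSpectrumError
from finecomp.possumm import CorrelationOperator

from conftest import dense_corr_oracle, random_sparse_matrix


def matrix_from_dense(dense, bin_size=500):
    n = dense.shape[0]
    bins = fc.BinTable("chr1", bin_size, n)
    iu = np.triu_indices(n)
    vals = dense[iu]
    keep = vals != 0
    return fc.ContactMatrix.from_coo(bins, iu[0][keep], iu[1][keep], vals[keep])


class TestVarianceFilter:
    def test_constant_and_zero_columns_excluded(self):
        # an all-zero row/column is dropped; informative columns survive
        dense = np.array(
            [[0.0, 1, 2, 0], [1, 0, 3, 0], [2, 3, 1, 0], [0, 0, 0, 0]]
        )
        stats = fc.filter_zero_variance(matrix_from_dense(dense))
        assert stats.kept.tolist() == [0, 1, 2]

    def test_filter_iterates_to_fixed_point(self):
        # removing the zero column leaves two constant columns, whose removal
        # collapses the matrix below two columns: degenerate overall
        dense = np.array(
            [[5.0, 5, 5, 0], [5, 5, 5, 0], [5, 5, 1, 0], [0, 0, 0, 0]]
        )
        with pytest.raises(DegenerateMatrixError):
            fc.filter_zero_variance(matrix_from_dense(dense))

    def test_population_sigma_convention(self):
        # column [0, 0, 4]: mean 4/3, population sigma sqrt(32/9)
        dense = np.array([[0.0, 1, 0], [1, 0, 0], [0, 0, 4]])
        stats = fc.filter_zero_variance(matrix_from_dense(dense))
        assert stats.mean[2] == pytest.approx(4 / 3)
        assert stats.sigma[2] == pytest.approx(np.sqrt(32 / 9))

    def test_degenerate_matrix_raises(self):
        dense = np.diag([3.0, 0.0, 0.0])
        with pytest.raises(DegenerateMatrixError):
            fc.filter_zero_variance(matrix_from_dense(dense))


class TestImplicitMatvec:
    def test_identical_columns_standardized_self_dot_is_n(self):
        # columns 1 and 2 identical -> correlation 1; diagonal of A = n
        dense = np.array([[0.0, 1, 1], [1, 2, 2], [1, 2, 2]])
        m = matrix_from_dense(dense)
        stats = fc.filter_zero_variance(m)
        y = fc.implicit_corr_matvec(stats, m, np.array([0.0, 1.0, 0.0]))
        assert y[1] == pytest.approx(3.0)
        assert y[2] == pytest.approx(3.0)

    def test_anticorrelated_columns_cancel(self):
        dense = np.array([[1.0, 0], [0, 1]])
        m = matrix_from_dense(dense)
        stats = fc.filter_zero_variance(m)
        y = fc.implicit_corr_matvec(stats, m, np.array([1.0, 1.0]))
        assert np.allclose(y, 0.0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_correlation_product(self, seed):
        m = random_sparse_matrix(6, 0.5, seed + 10)
        kept, w, V = dense_corr_oracle(m)
        sub = m.dense()[np.ix_(kept, kept)]
        Y = (sub - sub.mean(axis=0)) / sub.std(axis=0)
        A = Y.T @ Y
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(kept.size)
        op = CorrelationOperator(m)
        assert np.linalg.norm(op.matvec(x) - A @ x) < 1e-10 * np.linalg.norm(A @ x)

    def test_pearson_mode_matches_dense_residual_oracle(self):
        m = random_sparse_matrix(50, 0.2, 3)
        op = CorrelationOperator(m, mode="pearson")
        e = m.distance_means()
        D = m.dense()
        n = m.n_bins
        dd = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        B = np.where(e[dd] > 0, (D - e[dd]) / np.sqrt(np.where(e[dd] > 0, e[dd], 1)), 0)
        Bk = B[np.ix_(op.kept, op.kept)]
        Y = (Bk - Bk.mean(axis=0)) / Bk.std(axis=0)
        A = Y.T @ Y
        x = np.random.default_rng(1).standard_normal(op.dim)
        assert np.linalg.norm(op.matvec(x) - A @ x) < 1e-9 * np.linalg.norm(A @ x)

    def test_no_dense_square_array_is_held(self):
        """The operator keeps only sparse data and O(n) vectors."""
        m = random_sparse_matrix(200, 0.05, 4)
        op = CorrelationOperator(m, mode="pearson")
        for attr, val in vars(op).items():
            if isinstance(val, np.ndarray):
                assert val.ndim == 1, f"{attr} is a dense 2-D array"


class TestPowerIteration:
    def test_rank_one_spectrum(self):
        s = np.array([1.0, 1, -1, -1]) / 2
        A = 12 * np.outer(s, s)
        res = fc.power_top(lambda x: A @ x, dim=4, seed=0)
        assert res.converged
        assert res.value == pytest.approx(12.0)
        assert abs(res.vector @ s) == pytest.approx(1.0)

    def test_degenerate_spectrum_gives_valid_lambda(self):
        res = fc.power_top(lambda x: 2.0 * x, dim=2, seed=0)
        assert res.value == pytest.approx(2.0)
        with pytest.raises(DegenerateSpectrumError):
            fc.error_bound(2.0, 2.0, res.vector, lambda x: 2.0 * x)

    def test_matches_dense_oracle_on_random_instance(self):
        m = random_sparse_matrix(200, 0.05, 7)
        kept, w, V = dense_corr_oracle(m)
        op = CorrelationOperator(m)
        res = fc.power_top(op, dim=op.dim, tol=1e-11, seed=1)
        assert abs(res.value - w[0]) / w[0] < 1e-8
        assert abs(res.vector @ V[:, 0]) > 1 - 1e-8


class TestDeflation:
    def test_rank_one_gives_zero_second_eigenvalue(self):
        s = np.array([1.0, 1, -1, -1]) / 2
        A = 12 * np.outer(s, s)
        res = fc.deflate_next(lambda x: A @ x, s[:, None], dim=4, seed=0)
        assert res.value == pytest.approx(0.0, abs=1e-10)

    def test_lambda_converges_in_degenerate_subspace(self):
        # spectrum {6, 3, 3}: lambda_2 estimable though v_2 is not unique
        V = np.linalg.qr(np.random.default_rng(0).standard_normal((3, 3)))[0]
        A = V @ np.diag([6.0, 3.0, 3.0]) @ V.T
        top = fc.power_top(lambda x: A @ x, dim=3, tol=1e-12, seed=1)
        res = fc.deflate_next(lambda x: A @ x, top.vector[:, None], dim=3,
                              tol=1e-12, seed=1)
        assert res.value == pytest.approx(3.0, abs=1e-6)

    def test_top_four_match_oracle(self):
        m = random_sparse_matrix(120, 0.08, 9)
        kept, w, V = dense_corr_oracle(m)
        res = fc.possumm(m, k=4, tol=1e-11, seed=2)
        assert np.allclose(res.values, w[:4], rtol=1e-8)

    def test_requires_orthonormal_basis(self):
        with pytest.raises(ValueError):
            fc.deflate_next(lambda x: x, np.array([[2.0], [0.0]]), dim=2)


class TestErrorBound:
    def test_exact_eigenvector_gives_zero(self):
        A = np.diag([5.0, 2.0, 1.0])
        v = np.array([1.0, 0, 0])
        assert fc.error_bound(5.0, 2.0, v, lambda x: A @ x) == pytest.approx(0.0)

    def test_bound_dominates_true_error(self):
        A = np.diag([5.0, 2.0, 1.0])
        v = np.array([1.0, 0.05, -0.03])
        v /= np.linalg.norm(v)
        lam = v @ A @ v
        bound = fc.error_bound(lam, 2.0, v, lambda x: A @ x)
        true_err = np.linalg.norm(v - np.array([1.0, 0, 0]))
        assert true_err <= bound


class TestPossumm:
    def test_block_plaid_sign_pattern(self):
        # two perfectly plaid blocks: v1 signs reproduce the block labels
        labels = np.array([1] * 5 + [-1] * 5)
        dense = np.where(np.equal.outer(labels, labels), 4.0, 1.0)
        res = fc.possumm(matrix_from_dense(dense), k=1, seed=0)
        v = res.vectors[:, 0]
        v = v if v[0] > 0 else -v
        assert np.array_equal(np.sign(v), labels)

    def test_missing_rows_reexpanded_as_nan(self):
        rng = np.random.default_rng(3)
        dense = rng.integers(0, 5, (30, 30)).astype(float)
        dense = np.triu(dense) + np.triu(dense, 1).T
        dead = [2, 5, 11, 17, 23]
        dense[dead, :] = 0
        dense[:, dead] = 0
        res = fc.possumm(matrix_from_dense(dense), k=1, seed=0)
        assert res.vectors.shape == (30, 1)
        assert np.isnan(res.vectors[dead, 0]).all()
        assert np.isfinite(np.delete(res.vectors[:, 0], dead)).all()

    def test_k_bounds(self):
        m = random_sparse_matrix(20, 0.4, 1)
        with pytest.raises(ValueError):
            fc.possumm(m, k=0)
        with pytest.raises(ValueError):
            fc.possumm(m, k=5)

    def test_psd_rayleigh_quotients(self):
        m = random_sparse_matrix(80, 0.1, 5)
        op = CorrelationOperator(m)
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.standard_normal(op.dim)
            x /= np.linalg.norm(x)
            assert x @ op.matvec(x) >= -1e-9

    def test_global_scale_invariance(self):
        """Correlation standardization removes any positive scaling of X."""
        m = random_sparse_matrix(60, 0.15, 6)
        r1 = fc.possumm(m, k=2, tol=1e-11, seed=4)
        r2 = fc.possumm(m.scaled(37.5), k=2, tol=1e-11, seed=4)
        assert np.allclose(r1.values, r2.values, rtol=1e-10)
        v1, v2 = r1.vectors[:, 0], r2.vectors[:, 0]
        ok = np.isfinite(v1)
        assert abs(v1[ok] @ v2[ok]) == pytest.approx(1.0, abs=1e-10)
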