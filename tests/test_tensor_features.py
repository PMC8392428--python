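"""Tensor stacking, CP-ALS, rank selection, and frozen-factor features."""

import numpy as np
import pytest
from scipy.optimize import least_squares

from epitensor.config import RankSelectionError, SizeError
from epitensor.tensor_features import (
    cp_als,
    extract_feature,
    feature_matrix,
    fit_reference,
    khatri_rao,
    reconstruct,
    relative_error,
    select_rank,
    stack_tensors,
    unfold,
)


def _rank_k_tensor(rng, k, shape=(23, 23, 6)):
    I, J, K = shape
    return sum(
        np.einsum("i,j,k->ijk", rng.random(I), rng.random(J), rng.random(K))
        for _ in range(k)
    )


def _random_binary_tensor(rng, shape=(23, 23, 4), p=0.4):
    m = rng.random((shape[0], shape[1])) < p
    a = np.triu(m, 1)
    slice_ = (a + a.T).astype(float)
    out = np.stack(
        [np.abs(slice_ - (rng.random(slice_.shape) < 0.05)) for _ in range(shape[2])],
        axis=-1,
    )
    return out


class TestUnfoldingConventions:
    def test_mode1_unfolding_matches_khatri_rao_identity(self):
        # X_(1) = A (C ⊙ B)^T for a CP tensor
        rng = np.random.default_rng(0)
        A, B, C = rng.random((4, 3)), rng.random((5, 3)), rng.random((6, 3))
        X = np.einsum("ir,jr,kr->ijk", A, B, C)
        np.testing.assert_allclose(
            unfold(X, 0), A @ khatri_rao(C, B).T, atol=1e-12
        )

    def test_mode3_unfolding_matches_khatri_rao_identity(self):
        rng = np.random.default_rng(1)
        A, B, C = rng.random((4, 3)), rng.random((5, 3)), rng.random((6, 3))
        X = np.einsum("ir,jr,kr->ijk", A, B, C)
        np.testing.assert_allclose(
            unfold(X, 2), C @ khatri_rao(B, A).T, atol=1e-12
        )


class TestStackTensors:
    @pytest.mark.parametrize(
        "n,num,stride,expected",
        [(6, 3, 3, 2), (7, 3, 3, 2), (674, 6, 6, 112), (5, 3, 1, 3)],
    )
    def test_counts(self, n, num, stride, expected):
        series = [np.zeros((23, 23), dtype=np.int8)] * n
        assert len(stack_tensors(series, num, stride)) == expected

    def test_slices_are_frontal(self):
        rng = np.random.default_rng(2)
        series = [(rng.random((5, 5)) < 0.5).astype(float) for _ in range(3)]
        X = stack_tensors(series, 3)[0]
        for k in range(3):
            np.testing.assert_array_equal(X[:, :, k], series[k])

    def test_too_few_raises(self):
        with pytest.raises(SizeError):
            stack_tensors([np.zeros((23, 23))], 3)


class TestCpAls:
    def test_exact_rank_one_recovery(self):
        rng = np.random.default_rng(3)
        a, b, c = rng.random(23), rng.random(23), rng.random(6)
        X = np.einsum("i,j,k->ijk", a, b, c)
        f = cp_als(X, R=1, seed=0)
        assert relative_error(X, f) < 1e-6
        lam_true = np.linalg.norm(a) * np.linalg.norm(b) * np.linalg.norm(c)
        assert abs(f.lam[0] - lam_true) < 1e-6

    def test_zero_tensor(self):
        f = cp_als(np.zeros((23, 23, 3)), R=2, seed=0)
        assert np.all(f.lam == 0)
        assert np.all(reconstruct(f) == 0)

    def test_error_monotone_per_iteration(self):
        rng = np.random.default_rng(4)
        for trial in range(20):
            X = _random_binary_tensor(rng)
            f = cp_als(X, R=5, seed=trial, tol=0.0, max_iter=60)
            trace = np.array(f.error_trace)
            assert np.all(np.diff(trace) <= 1e-12)

    def test_unit_norm_columns_where_lambda_positive(self):
        rng = np.random.default_rng(5)
        X = _rank_k_tensor(rng, 2)
        f = cp_als(X, R=2, seed=0)
        for M in (f.A, f.B, f.C):
            np.testing.assert_allclose(
                np.linalg.norm(M[:, f.lam > 0], axis=0), 1.0, atol=1e-9
            )


class TestRelativeError:
    def test_exact_fit_is_zero(self):
        rng = np.random.default_rng(6)
        X = _rank_k_tensor(rng, 1)
        f = cp_als(X, R=1, seed=0)
        assert relative_error(X, f) < 1e-10

    def test_zero_reconstruction_of_nonzero_tensor_is_one(self):
        X = np.zeros((3, 3, 2))
        X[0, 1, 0] = 1.0
        f = cp_als(np.zeros((3, 3, 2)), R=1, seed=0)
        assert relative_error(X, f) == pytest.approx(1.0)

    def test_single_cell_difference(self):
        # binary tensor with 10 ones; reconstruction off by 1 in one cell
        X = np.zeros((5, 5, 2))
        idx = [(0, 1, 0), (1, 2, 0), (2, 3, 0), (3, 4, 0), (0, 2, 1),
               (1, 3, 1), (2, 4, 1), (0, 3, 0), (1, 4, 1), (0, 4, 0)]
        for i, j, k in idx:
            X[i, j, k] = 1.0
        Xhat = X.copy()
        Xhat[4, 4, 1] += 1.0
        err = np.linalg.norm(X - Xhat) / np.linalg.norm(X)
        assert err == pytest.approx(1 / np.sqrt(10))


class TestSelectRank:
    def test_rank_one_tensor_gives_R1(self):
        rng = np.random.default_rng(7)
        X = _rank_k_tensor(rng, 1)
        R, f = select_rank(X, seed=0)
        assert R == 1 and relative_error(X, f) < 0.05

    def test_rank_two_tensor_gives_R2(self):
        rng = np.random.default_rng(8)
        X = _rank_k_tensor(rng, 2)
        # brute-force confirmation that R=1 is insufficient for this tensor
        assert relative_error(X, cp_als(X, 1, seed=0)) >= 0.05
        R, f = select_rank(X, seed=0)
        assert R == 2 and relative_error(X, f) < 0.05

    def test_zero_tensor_R1_convention(self):
        R, _ = select_rank(np.zeros((23, 23, 3)), seed=0)
        assert R == 1

    def test_exhaustion_raises_with_trace(self):
        rng = np.random.default_rng(9)
        X = _random_binary_tensor(rng)
        with pytest.raises(RankSelectionError) as exc:
            select_rank(X, err_thresh=1e-9, seed=0, R_max=3, max_iter=30)
        assert len(exc.value.error_trace) == 3

    def test_error_trace_non_increasing_in_R(self):
        rng = np.random.default_rng(10)
        X = _random_binary_tensor(rng)
        errs = [relative_error(X, cp_als(X, R, seed=3)) for R in range(1, 8)]
        assert all(a >= b - 1e-6 for a, b in zip(errs, errs[1:]))


class TestFitReference:
    def test_rank_one_reference_single_column(self):
        rng = np.random.default_rng(11)
        X = _rank_k_tensor(rng, 1)
        A, B, R = fit_reference(X, seed=0)
        assert R == 1 and A.shape == (23, 1) and B.shape == (23, 1)

    def test_deterministic(self):
        rng = np.random.default_rng(12)
        X = _random_binary_tensor(rng, p=0.5)
        A1, B1, R1 = fit_reference(X, seed=5)
        A2, B2, R2 = fit_reference(X, seed=5)
        assert R1 == R2
        np.testing.assert_array_equal(A1, A2)
        np.testing.assert_array_equal(B1, B2)

    def test_unit_norm_columns(self):
        rng = np.random.default_rng(13)
        X = _random_binary_tensor(rng, p=0.5)
        A, B, _ = fit_reference(X, seed=1)
        np.testing.assert_allclose(np.linalg.norm(A, axis=0), 1.0, atol=1e-9)
        np.testing.assert_allclose(np.linalg.norm(B, axis=0), 1.0, atol=1e-9)


class TestExtractFeature:
    def test_self_consistency_on_reference(self):
        rng = np.random.default_rng(14)
        X = _random_binary_tensor(rng, p=0.5)
        R, f = select_rank(X, seed=2)
        feat = extract_feature(X, f.A, f.B)
        expected = (f.C * f.lam).mean(axis=0)
        np.testing.assert_allclose(feat, expected, atol=1e-6)

    def test_zero_tensor_zero_feature(self):
        rng = np.random.default_rng(15)
        A, B, _ = fit_reference(_rank_k_tensor(rng, 2), seed=0)
        feat = extract_feature(np.zeros((23, 23, 6)), A, B)
        np.testing.assert_allclose(feat, 0.0, atol=1e-12)

    def test_matches_frozen_factor_als(self):
        # iterative ALS with A and B updates skipped must agree with the
        # one-shot least-squares solve
        rng = np.random.default_rng(16)
        X0 = _random_binary_tensor(rng, shape=(23, 23, 4), p=0.5)
        A, B, R = fit_reference(X0, seed=0)
        X = _random_binary_tensor(rng, shape=(23, 23, 4), p=0.5)
        kr = khatri_rao(B, A)
        C = rng.random((4, R))
        for _ in range(50):  # frozen-factor ALS: only the C update runs
            C = np.linalg.lstsq(kr, unfold(X, 2).T, rcond=None)[0].T
        np.testing.assert_allclose(
            extract_feature(X, A, B), C.mean(axis=0), atol=1e-8
        )

    def test_matches_numeric_optimizer_on_2x2x2(self):
        # independent oracle: scipy minimizes the reconstruction error over C
        rng = np.random.default_rng(17)
        for trial in range(5):
            A = rng.random((2, 2))
            A /= np.linalg.norm(A, axis=0)
            B = rng.random((2, 2))
            B /= np.linalg.norm(B, axis=0)
            X = rng.random((2, 2, 2))

            def resid(c_flat):
                C = c_flat.reshape(2, 2)
                return (X - np.einsum("ir,jr,kr->ijk", A, B, C)).ravel()

            res = least_squares(
                resid, rng.random(4), method="lm",
                xtol=1e-15, ftol=1e-15, gtol=1e-15,
            )
            C_opt = res.x.reshape(2, 2)
            np.testing.assert_allclose(
                extract_feature(X, A, B), C_opt.mean(axis=0), atol=1e-6
            )


class TestFeatureMatrix:
    def test_shape_and_permutation(self):
        rng = np.random.default_rng(18)
        A, B, R = fit_reference(_random_binary_tensor(rng, p=0.5), seed=0)
        tensors = [_random_binary_tensor(rng) for _ in range(6)]
        F = feature_matrix(tensors, A, B)
        assert F.shape == (6, R)
        perm = [3, 1, 0, 2, 5, 4]
        np.testing.assert_allclose(
            feature_matrix([tensors[p] for p in perm], A, B), F[perm], atol=1e-12
        )

    def test_equal_tensors_equal_rows(self):
        rng = np.random.default_rng(19)
        A, B, _ = fit_reference(_random_binary_tensor(rng, p=0.5), seed=0)
        X = _random_binary_tensor(rng)
        F = feature_matrix([X, X, X], A, B)
        assert np.all(F[0] == F[1]) and np.all(F[1] == F[2])
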