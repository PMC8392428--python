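"""Dynamic-network tensors, CP decomposition by ALS, and feature extraction.

Consecutive functional brain networks are stacked along time into third-order
binary tensors ``X`` of shape I x J x K (I = J = channels, K = num networks).
Each tensor is approximated by a CP (CANDECOMP/PARAFAC) model

    X  ~=  sum_r  lambda_r  a_r o b_r o c_r

fitted by alternating least squares (ALS) on the mode-n unfoldings, with the
component count R grown from 1 until the relative Frobenius reconstruction
error drops below a threshold (0.05 by default).

Feature extraction fixes the channel factors: the factor matrices A and B of
one reference tensor are frozen, and for every subsequent tensor only the
temporal factor C (and the weights lambda) are re-estimated — a single linear
least-squares solve, since with A and B fixed the CP objective is quadratic
in C.  The feature vector of a tensor is the column mean of
``F = C_normalized * diag(lambda)`` (equivalently, of the unnormalized
least-squares solution for C), of length R.

Mode-n unfoldings follow the convention in which the mode-1 unfolding
satisfies ``X_(1) = A (C ⊙ B)^T`` with ``⊙`` the column-wise Khatri-Rao
product.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import NumericalError, RankSelectionError, SizeError

logger = logging.getLogger("epitensor")


# ---------------------------------------------------------------------------
# Tensor construction
# ---------------------------------------------------------------------------


def stack_tensors(
    adj_series: list[np.ndarray], num: int, stride: int | None = None
) -> list[np.ndarray]:
    """Stack runs of ``num`` consecutive networks into I x J x num tensors.

    Tensor t holds slices ``[t*stride, t*stride + num)``; trailing networks
    that do not fill a tensor are dropped.  ``stride`` defaults to ``num``
    (disjoint tensors).
    """
    stride = num if stride is None else stride
    if stride < 1 or num < 1:
        raise ValueError("num and stride must be positive")
    n = len(adj_series)
    if n < num:
        raise SizeError(f"{n} networks cannot fill one tensor of {num} slices")
    count = (n - num) // stride + 1
    return [
        np.stack(adj_series[t * stride : t * stride + num], axis=-1).astype(float)
        for t in range(count)
    ]


# ---------------------------------------------------------------------------
# CP decomposition by alternating least squares
# ---------------------------------------------------------------------------


@dataclass
class CpFactors:
    """Factor matrices and weights of a CP model of an I x J x K tensor."""

    A: np.ndarray  # I x R
    B: np.ndarray  # J x R
    C: np.ndarray  # K x R
    lam: np.ndarray  # length R, nonnegative
    R: int
    seed: int
    error_trace: list[float] = field(default_factory=list)
    n_iter: int = 0


def unfold(X: np.ndarray, mode: int) -> np.ndarray:
    """Mode-n unfolding (matricization) of a third-order tensor."""
    return np.reshape(
        np.moveaxis(X, mode, 0), (X.shape[mode], -1), order="F"
    )


def khatri_rao(U: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Column-wise Kronecker product of U (m x R) and V (n x R): (m n) x R."""
    if U.shape[1] != V.shape[1]:
        raise ValueError("Khatri-Rao factors need equal column counts")
    return (U[:, None, :] * V[None, :, :]).reshape(-1, U.shape[1])


def _ls_update(Xn: np.ndarray, kr: np.ndarray, gram: np.ndarray) -> np.ndarray:
    """Exact least-squares factor update  argmin_F ||Xn - F kr^T||_F."""
    rhs = Xn @ kr
    try:
        return np.linalg.solve(gram.T, rhs.T).T
    except np.linalg.LinAlgError:
        return rhs @ np.linalg.pinv(gram)


def cp_als(
    X: np.ndarray,
    R: int,
    seed: int,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> CpFactors:
    """Fit a rank-R CP model to ``X`` by alternating least squares.

    Factors are initialized uniformly on [0, 1) from ``seed``.  Each sweep
    solves the three exact least-squares subproblems in turn, so the
    reconstruction error is non-increasing per iteration; the sweep stops
    when the relative error changes by less than ``tol`` or after
    ``max_iter`` sweeps.  Columns are normalized at the end with the norms
    absorbed into ``lam``.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    X = np.asarray(X, dtype=float)
    I, J, K = X.shape
    rng = np.random.default_rng(seed)
    A = rng.random((I, R))
    B = rng.random((J, R))
    C = rng.random((K, R))
    X1, X2, X3 = unfold(X, 0), unfold(X, 1), unfold(X, 2)
    norm_x = np.linalg.norm(X)

    trace: list[float] = []
    prev = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        AtA, BtB, CtC = A.T @ A, B.T @ B, C.T @ C
        A = _ls_update(X1, khatri_rao(C, B), CtC * BtB)
        AtA = A.T @ A
        B = _ls_update(X2, khatri_rao(C, A), CtC * AtA)
        BtB = B.T @ B
        kr_ba = khatri_rao(B, A)
        C = _ls_update(X3, kr_ba, BtB * AtA)
        CtC = C.T @ C
        if not (np.isfinite(A).all() and np.isfinite(B).all() and np.isfinite(C).all()):
            raise NumericalError(f"non-finite CP factors at iteration {it}")
        # ||X - Xhat||^2 = ||X||^2 - 2 <X, Xhat> + ||Xhat||^2, all in factor space
        inner = float(np.sum((X3 @ kr_ba) * C))
        norm_hat2 = float(np.sum((AtA * BtB) * CtC))
        resid2 = max(norm_x**2 - 2.0 * inner + norm_hat2, 0.0)
        err = np.sqrt(resid2) / norm_x if norm_x > 0 else 0.0
        trace.append(err)
        if abs(prev - err) < tol:
            break
        prev = err

    norms = [np.linalg.norm(M, axis=0) for M in (A, B, C)]
    lam = norms[0] * norms[1] * norms[2]
    out = []
    for M, nrm in zip((A, B, C), norms):
        safe = np.where(nrm > 0, nrm, 1.0)
        out.append(M / safe)
    A, B, C = out
    return CpFactors(A=A, B=B, C=C, lam=lam, R=R, seed=seed, error_trace=trace, n_iter=it)


def reconstruct(f: CpFactors) -> np.ndarray:
    """Dense tensor of the CP model ``sum_r lam_r a_r o b_r o c_r``."""
    return np.einsum("ir,jr,kr,r->ijk", f.A, f.B, f.C, f.lam)


def relative_error(X: np.ndarray, f: CpFactors) -> float:
    """Relative Frobenius reconstruction error ``||X - Xhat|| / ||X||``.

    A zero tensor with a zero reconstruction has error 0 by convention;
    a zero tensor with a nonzero reconstruction has error ``inf``.
    """
    X = np.asarray(X, dtype=float)
    Xhat = reconstruct(f)
    if X.shape != Xhat.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {Xhat.shape}")
    norm_x = np.linalg.norm(X)
    resid = np.linalg.norm(X - Xhat)
    if norm_x == 0:
        return 0.0 if resid == 0 else np.inf
    return resid / norm_x


def select_rank(
    X: np.ndarray,
    err_thresh: float = 0.05,
    seed: int = 0,
    R_max: int = 100,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> tuple[int, CpFactors]:
    """Smallest R in 1..R_max whose CP fit has relative error < err_thresh.

    R grows by 1 from 1, one ALS run per R (same seed).  Raises
    :class:`RankSelectionError` carrying the error trace when ``R_max`` is
    exhausted.  A zero tensor returns R = 1 (its error is 0 by convention).
    """
    if not 0 < err_thresh < 1:
        raise ValueError("err_thresh must lie in (0, 1)")
    trace: list[float] = []
    for R in range(1, R_max + 1):
        f = cp_als(X, R, seed=seed, tol=tol, max_iter=max_iter)
        err = relative_error(X, f)
        trace.append(err)
        if err < err_thresh:
            logger.info("rank search: R=%d reaches error %.4f", R, err)
            return R, f
    raise RankSelectionError(
        f"no R <= {R_max} reaches relative error < {err_thresh}", trace
    )


# ---------------------------------------------------------------------------
# Partially-fixed-factor feature extraction
# ---------------------------------------------------------------------------


def fit_reference(
    X0: np.ndarray,
    err_thresh: float = 0.05,
    seed: int = 0,
    R_max: int = 100,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Decompose the reference tensor and freeze its channel factors.

    Runs the error-driven rank search on ``X0`` and returns
    ``(A_fixed, B_fixed, R)`` with unit-norm columns; these stay fixed for
    every subsequent feature extraction.
    """
    R, f = select_rank(
        X0, err_thresh=err_thresh, seed=seed, R_max=R_max, tol=tol, max_iter=max_iter
    )
    logger.info("reference tensor fixed at R=%d components", R)
    return f.A, f.B, R


def extract_feature(
    X: np.ndarray, A_fixed: np.ndarray, B_fixed: np.ndarray
) -> np.ndarray:
    """Length-R feature of one tensor with the channel factors frozen.

    With A and B fixed, the optimal temporal factor solves the linear
    least-squares problem ``X_(3) ~= C (B ⊙ A)^T`` in closed form (no
    iteration).  The weights ``lam_r = ||C[:, r]||`` are split off and the
    feature is the column mean of ``F = C_normalized * diag(lam)``, which
    equals the column mean of the unnormalized solution.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] != A_fixed.shape[0] or X.shape[1] != B_fixed.shape[0]:
        raise ValueError("tensor shape does not match the fixed factors")
    kr = khatri_rao(B_fixed, A_fixed)  # (I J) x R
    X3 = unfold(X, 2)  # K x (I J)
    gram = kr.T @ kr
    rhs = X3 @ kr
    try:
        F = np.linalg.solve(gram.T, rhs.T).T  # K x R, = C * diag(lam)
    except np.linalg.LinAlgError:
        logger.info("rank-deficient Khatri-Rao product; using pseudoinverse")
        F = rhs @ np.linalg.pinv(gram)
    return F.mean(axis=0)


def feature_matrix(
    tensors: list[np.ndarray], A_fixed: np.ndarray, B_fixed: np.ndarray
) -> np.ndarray:
    """One feature row per tensor (tensors x R), order preserved."""
    if not tensors:
        raise ValueError("tensor list is empty")
    return np.vstack([extract_feature(X, A_fixed, B_fixed) for X in tensors])
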