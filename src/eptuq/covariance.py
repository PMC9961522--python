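"""Shrinkage covariance estimation and its propagation through the operator.

With only K scans against ~10^4 voxels, the experimental covariance of the
mean phase (or mean conductivity) map is rank-deficient and badly estimated.
Following the James–Stein shrinkage approach, the estimate used everywhere is

    Sigma = lambda * S  +  (1 - lambda) * diag(S),

where ``S`` is the experimental covariance of the mean and ``lambda`` in
[0, 1] is chosen analytically (Schaefer–Strimmer estimator on the correlation
scale) to minimize the expected Frobenius error.  The matrix is never
materialized densely at phase resolution: it is carried as a rank-(K-1)
factor plus a diagonal, and its propagation through the sparse reconstruction
operator ``A`` keeps the same structure (low-rank factor ``A X`` plus the
sparse symmetric ``A diag A^T``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from .sg import LaplacianOperator


@dataclass
class MeanCovarianceFactor:
    """Factored covariance of a voxelwise mean over K scans.

    ``X`` holds the centered scans scaled by ``1 / sqrt(K (K - 1))`` so that
    the experimental covariance of the mean is ``S = X X^T``; ``diag`` is its
    diagonal.  After shrinkage the implied estimate is
    ``lam * X X^T + (1 - lam) * diag``.
    """

    X: np.ndarray          # (N, K)
    diag: np.ndarray       # (N,)
    K: int
    lam: float | None = None

    @property
    def dim(self) -> int:
        return self.X.shape[0]

    def implied_dense(self) -> np.ndarray:
        """Dense shrunken covariance; for tests on small problems only."""
        lam = 1.0 if self.lam is None else self.lam
        s = self.X @ self.X.T
        return lam * s + (1.0 - lam) * np.diag(np.diag(s))


def covariance_of_mean(scans: np.ndarray) -> MeanCovarianceFactor:
    """Experimental covariance of the voxelwise mean of ``scans`` (K, N).

    ``S = 1/(K(K-1)) sum_k (p_k - pbar)(p_k - pbar)^T`` in factored form.
    """
    scans = np.atleast_2d(np.asarray(scans, dtype=float))
    k, _ = scans.shape
    if k < 2:
        raise ValueError("covariance of the mean needs at least 2 scans")
    dev = scans - scans.mean(axis=0)
    x = dev.T / np.sqrt(k * (k - 1.0))
    return MeanCovarianceFactor(X=x, diag=np.sum(x * x, axis=1), K=k)


def shrinkage_intensity(factor: MeanCovarianceFactor) -> float:
    """Analytic shrinkage coefficient ``lam`` weighting the experimental matrix.

    Computed on the correlation scale: with ``r_ij`` the sample correlations,
    the optimal weight of the diagonal target is
    ``lam_SS = sum_{i!=j} Var(r_ij) / sum_{i!=j} r_ij^2`` (clipped to [0, 1])
    and ``lam = 1 - lam_SS``.  Because correlations are scale-free, the
    1/(K(K-1)) normalization of the factor cancels.  When every off-diagonal
    correlation vanishes the estimate collapses onto the diagonal (lam = 0).
    """
    k = factor.K
    if k < 3:
        raise ValueError("shrinkage intensity needs at least 3 scans")
    dev = factor.X * np.sqrt(k * (k - 1.0))       # (N, K) centered scans
    var = np.sum(dev * dev, axis=1) / (k - 1.0)
    zero = var <= 0.0
    if np.any(zero):
        raise ValueError(
            "zero-variance voxels prevent forming correlations: "
            f"{np.flatnonzero(zero)[:10]}"
        )
    w = dev / np.sqrt(var)[:, None]               # standardized, (N, K)
    n_vox = w.shape[0]

    g = w.T @ w                                   # (K, K) Gram matrix
    sum_r2_all = np.sum(g * g) / (k - 1.0) ** 2   # = sum_ij r_ij^2
    sum_r2_off = sum_r2_all - n_vox               # r_ii == 1 exactly

    # sum over all voxel pairs of the centered second moment of w_i w_j
    s_k = np.sum(w * w, axis=0)                   # (K,)
    total = np.sum(s_k * s_k) - np.sum(g * g) / k
    # remove the i == j contribution
    diag_term = np.sum(w**4) - (k - 1.0) ** 2 * n_vox / k
    sum_var_off = k / (k - 1.0) ** 3 * (total - diag_term)

    if sum_r2_off <= 0.0:
        return 0.0
    lam_ss = float(np.clip(sum_var_off / sum_r2_off, 0.0, 1.0))
    return 1.0 - lam_ss


class PropagatedCovariance:
    """Covariance in low-rank-plus-sparse form with the solves the averages need.

    Represents ``Sigma = L L^T + S`` with ``L`` an (N, K) factor and ``S`` a
    sparse symmetric matrix; exposes ``diagonal``, ``quadratic_form`` and
    ``solve`` (sparse LU on ``S`` plus a rank-K Woodbury update).
    """

    def __init__(self, low_rank: np.ndarray, sparse_part: sparse.spmatrix,
                 lam: float, K: int):
        self.low_rank = np.asarray(low_rank, dtype=float)
        self.sparse_part = sparse.csr_matrix(sparse_part)
        if self.sparse_part.shape[0] != self.low_rank.shape[0]:
            raise ValueError("low-rank factor and sparse part dimensions differ")
        self.lam = float(lam)
        self.K = int(K)
        self._lu = None

    @property
    def dim(self) -> int:
        return self.low_rank.shape[0]

    def diagonal(self) -> np.ndarray:
        return np.sum(self.low_rank**2, axis=1) + self.sparse_part.diagonal()

    def quadratic_form(self, v: np.ndarray) -> float:
        v = np.asarray(v, dtype=float)
        if v.shape != (self.dim,):
            raise ValueError(f"vector length {v.shape} != {self.dim}")
        lt_v = self.low_rank.T @ v
        return float(lt_v @ lt_v + v @ (self.sparse_part @ v))

    def _factorize(self):
        if self._lu is None:
            s = self.sparse_part.tocsc()
            if s.nnz == 0 or sparse.linalg.norm(s) == 0.0:
                raise np.linalg.LinAlgError(
                    "sparse part of the covariance is zero (lambda = 1): the "
                    "rank-deficient estimate cannot be inverted"
                )
            try:
                self._lu = splu(s, permc_spec="MMD_AT_PLUS_A",
                                options={"SymmetricMode": True})
            except RuntimeError as exc:  # singular factorization
                raise np.linalg.LinAlgError(
                    f"sparse covariance part is singular: {exc}"
                ) from exc
        return self._lu

    def matvec(self, v: np.ndarray) -> np.ndarray:
        return self.sparse_part @ v + self.low_rank @ (self.low_rank.T @ v)

    def solve(self, rhs: np.ndarray, rtol: float = 1e-10) -> np.ndarray:
        """``Sigma^{-1} rhs``: preconditioned CG, LU/Woodbury as fallback.

        Conjugate gradient on the full low-rank-plus-sparse matvec with a
        diagonal (Jacobi) preconditioner converges in a few hundred
        iterations at production sizes; when it stalls the solve falls back
        to a sparse LU of the sparse part plus a rank-K Woodbury update.
        """
        rhs = np.asarray(rhs, dtype=float)
        if rhs.shape != (self.dim,):
            raise ValueError(f"rhs length {rhs.shape} != {self.dim}")
        d = self.diagonal()
        if np.all(d > 0):
            n = self.dim
            a = sparse.linalg.LinearOperator((n, n), matvec=self.matvec)
            m = sparse.linalg.LinearOperator((n, n), matvec=lambda v: v / d)
            y, info = sparse.linalg.cg(a, rhs, M=m, rtol=rtol, atol=0.0,
                                       maxiter=20 * n)
            if info == 0:
                self._check_definite(rhs, y)
                return y
        y = self._solve_woodbury(rhs)
        self._check_definite(rhs, y)
        return y

    def _solve_woodbury(self, rhs: np.ndarray) -> np.ndarray:
        lu = self._factorize()
        y0 = lu.solve(rhs)
        l = self.low_rank
        if l.shape[1] == 0 or not np.any(l):
            return y0
        z = lu.solve(l)                            # (N, K)
        cap = np.eye(l.shape[1]) + l.T @ z         # capacitance matrix
        return y0 - z @ np.linalg.solve(cap, l.T @ y0)

    @staticmethod
    def _check_definite(rhs: np.ndarray, y: np.ndarray) -> None:
        if float(rhs @ y) < 0:
            raise np.linalg.LinAlgError(
                "covariance solve produced a negative quadratic form; "
                "the matrix is not positive definite"
            )

    def dense(self) -> np.ndarray:
        """Dense assembly; for tests on small problems only."""
        return self.low_rank @ self.low_rank.T + self.sparse_part.toarray()


def propagate_covariance(
    op: LaplacianOperator, factor: MeanCovarianceFactor, lam: float | None = None
) -> PropagatedCovariance:
    """Propagate a factored phase covariance through the linear operator.

    ``Sigma(s) = A (lam X X^T + (1 - lam) D) A^T`` represented exactly as
    ``(sqrt(lam) A X)(...)^T + (1 - lam) A D A^T`` without forming any dense
    N_p x N_p matrix.
    """
    if factor.dim != op.n_sources:
        raise ValueError(
            f"covariance dimension {factor.dim} != operator sources {op.n_sources}"
        )
    if lam is None:
        lam = 1.0 if factor.lam is None else factor.lam
    if not (0.0 <= lam <= 1.0):
        raise ValueError("lambda must lie in [0, 1]")
    a = op.matrix
    low_rank = np.sqrt(lam) * (a @ factor.X)
    if lam < 1.0:
        d = sparse.diags((1.0 - lam) * factor.diag)
        sparse_part = (a @ d) @ a.T
        sparse_part = (sparse_part + sparse_part.T) * 0.5
    else:
        n = op.n_targets
        sparse_part = sparse.csr_matrix((n, n))
    return PropagatedCovariance(low_rank, sparse_part, lam, factor.K)


def covariance_of_maps(
    maps: np.ndarray, shrink: bool = True
) -> tuple[PropagatedCovariance, float]:
    """Shrunken covariance of the mean of K conductivity maps (K, Ns).

    Used under reproducibility conditions, where each repositioned scan is
    reconstructed separately and the covariance is estimated directly on the
    conductivity maps (compared on matching regions of the phantom).
    Returns the covariance and the shrinkage coefficient.
    """
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    factor = covariance_of_mean(maps)
    # identical maps (up to roundoff relative to their magnitude): zero covariance
    tiny = (1e-12 * max(1.0, float(np.abs(maps).max()))) ** 2
    if np.all(factor.diag <= tiny):
        lam = 0.0
    elif not shrink or factor.K < 3:    # shrinkage needs >= 3 maps
        lam = 1.0
    else:
        lam = shrinkage_intensity(factor)
    low_rank = np.sqrt(lam) * factor.X
    sparse_part = sparse.diags((1.0 - lam) * factor.diag).tocsr()
    return PropagatedCovariance(low_rank, sparse_part, lam, factor.K), lam


def voxelwise_uncertainty(cov: PropagatedCovariance) -> np.ndarray:
    """Standard uncertainty per voxel: elementwise sqrt of the diagonal."""
    d = cov.diagonal()
    if np.any(d < -1e-12 * max(1.0, float(np.max(np.abs(d))))):
        raise ValueError("negative variance on the covariance diagonal")
    return np.sqrt(np.clip(d, 0.0, None))
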