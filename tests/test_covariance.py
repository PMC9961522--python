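"""Shrinkage covariance estimation, factored representation, propagation."""

import numpy as np
import pytest
from scipy import sparse

import eptuq as e
from eptuq.covariance import PropagatedCovariance


def eq5_dense(scans):
    """Independent oracle: literal covariance-of-the-mean over K scans."""
    scans = np.asarray(scans, dtype=float)
    k = scans.shape[0]
    pbar = scans.mean(axis=0)
    s = np.zeros((scans.shape[1], scans.shape[1]))
    for pk in scans:
        d = pk - pbar
        s += np.outer(d, d)
    return s / (k * (k - 1))


def test_covariance_of_mean_matches_hand_evaluation_k2():
    p = np.array([1.0, 2.0, -1.0])
    d = np.array([0.2, -0.1, 0.3])
    scans = np.stack([p + d, p - d])
    factor = e.covariance_of_mean(scans)
    dense = factor.X @ factor.X.T
    # K=2, scans p +/- d: sample variance is 2 d_i^2, so the covariance of
    # the mean is d_i d_j elementwise
    assert np.allclose(dense, np.outer(d, d), atol=1e-15)
    assert np.allclose(dense, eq5_dense(scans), atol=1e-15)


def test_covariance_of_mean_random_matches_oracle():
    rng = np.random.default_rng(0)
    scans = rng.normal(size=(6, 15))
    factor = e.covariance_of_mean(scans)
    assert np.allclose(factor.X @ factor.X.T, eq5_dense(scans), atol=1e-14)
    assert np.allclose(factor.diag, np.diag(eq5_dense(scans)), atol=1e-14)
    # centered deviations sum to zero across scans
    assert np.allclose(factor.X.sum(axis=1), 0.0, atol=1e-14)


def test_covariance_of_mean_identical_scans_is_zero():
    scans = np.tile(np.arange(5.0), (4, 1))
    factor = e.covariance_of_mean(scans)
    assert not np.any(factor.X)
    with pytest.raises(ValueError, match="at least 2"):
        e.covariance_of_mean(scans[:1])


def test_covariance_of_mean_iid_diagonal_scales_as_s2_over_k():
    rng = np.random.default_rng(1)
    s, k = 0.05, 25
    scans = rng.normal(scale=s, size=(k, 4000))
    factor = e.covariance_of_mean(scans)
    assert abs(factor.diag.mean() - s**2 / k) / (s**2 / k) < 0.05


def _orthogonal_deviation_scans(k, n):
    """Scans whose voxel deviations are exactly orthogonal -> all r_ij = 0.

    QR of [ones | random] yields columns 2..n+1 orthonormal and orthogonal to
    the ones vector, i.e. zero-mean across scans and mutually uncorrelated.
    """
    rng = np.random.default_rng(2)
    m = np.column_stack([np.ones(k), rng.normal(size=(k, k - 1))])
    q = np.linalg.qr(m)[0]
    return q[:, 1:n + 1] * 2.0  # (k scans, n voxels)


def test_shrinkage_zero_correlations_gives_lambda_zero():
    k, n = 8, 4
    scans = _orthogonal_deviation_scans(k, n)
    corr = np.corrcoef(scans.T)
    assert np.allclose(corr - np.eye(n), 0.0, atol=1e-10)
    factor = e.covariance_of_mean(scans)
    assert e.shrinkage_intensity(factor) == 0.0


def test_shrinkage_grows_with_sample_size_under_true_correlation():
    rng = np.random.default_rng(3)
    dim = 40
    c = np.linalg.cholesky(0.7 * np.ones((dim, dim)) + 0.3 * np.eye(dim))
    lam = {}
    for k in (10, 500):
        scans = rng.normal(size=(k, dim)) @ c.T
        lam[k] = e.shrinkage_intensity(e.covariance_of_mean(scans))
    assert 0.0 <= lam[10] <= lam[500] <= 1.0
    assert lam[500] > 0.9


def test_shrinkage_always_in_unit_interval():
    rng = np.random.default_rng(4)
    for _ in range(20):
        k = rng.integers(3, 12)
        n = rng.integers(2, 30)
        scans = rng.normal(size=(k, n)) * rng.uniform(0.1, 10)
        lam = e.shrinkage_intensity(e.covariance_of_mean(scans))
        assert 0.0 <= lam <= 1.0


def test_shrinkage_errors_on_degenerate_input():
    with pytest.raises(ValueError, match="at least 3"):
        e.shrinkage_intensity(e.covariance_of_mean(np.random.rand(2, 5)))
    scans = np.random.default_rng(5).normal(size=(5, 4))
    scans[:, 2] = 7.0  # zero-variance voxel
    with pytest.raises(ValueError, match="zero-variance"):
        e.shrinkage_intensity(e.covariance_of_mean(scans))


def test_shrinkage_reduces_frobenius_error():
    """With K=10 samples in dimension 200, the shrunk estimate beats the raw
    experimental covariance against the known truth in nearly every trial."""
    rng = np.random.default_rng(6)
    dim, k, trials = 200, 10, 100
    rho = 0.3 ** np.abs(np.subtract.outer(np.arange(dim), np.arange(dim)))
    c = np.linalg.cholesky(rho)
    truth = rho / k  # covariance of the mean of k unit-variance samples
    wins = 0
    for _ in range(trials):
        scans = rng.normal(size=(k, dim)) @ c.T
        factor = e.covariance_of_mean(scans)
        lam = e.shrinkage_intensity(factor)
        raw = factor.X @ factor.X.T
        shrunk = lam * raw + (1 - lam) * np.diag(np.diag(raw))
        if np.linalg.norm(shrunk - truth) <= np.linalg.norm(raw - truth):
            wins += 1
    assert wins >= 95


def test_propagation_lambda0_diagonal_closed_form(cross1_op):
    s = 0.01
    ns, np_ = cross1_op.n_targets, cross1_op.n_sources
    factor = e.MeanCovarianceFactor(
        X=np.zeros((np_, 1)), diag=np.full(np_, s**2), K=2)
    cov = e.propagate_covariance(cross1_op, factor, lam=0.0)
    rownorm2 = np.asarray(cross1_op.matrix.multiply(cross1_op.matrix).sum(axis=1)).ravel()
    assert np.allclose(cov.diagonal(), s**2 * rownorm2, rtol=1e-12)
    u = e.voxelwise_uncertainty(cov)
    assert np.allclose(u, s * np.sqrt(rownorm2), rtol=1e-12)


def test_propagation_lambda1_is_plain_propagation(cross1_op):
    rng = np.random.default_rng(7)
    scans = rng.normal(scale=0.01, size=(6, cross1_op.n_sources))
    factor = e.covariance_of_mean(scans)
    cov = e.propagate_covariance(cross1_op, factor, lam=1.0)
    a = cross1_op.matrix.toarray()
    dense_ref = a @ eq5_dense(scans) @ a.T
    assert np.allclose(cov.dense(), dense_ref, atol=1e-8 * np.abs(dense_ref).max())


@pytest.mark.parametrize("lam", [None, 0.0, 0.5, 1.0])
def test_factored_covariance_matches_dense_assembly(cross1_op, lam):
    """Diagonal, quadratic forms and solves of the factored representation
    agree with explicit dense assembly (small-grid check)."""
    rng = np.random.default_rng(8)
    scans = rng.normal(scale=0.01, size=(6, cross1_op.n_sources))
    factor = e.covariance_of_mean(scans)
    use_lam = e.shrinkage_intensity(factor) if lam is None else lam
    cov = e.propagate_covariance(cross1_op, factor, lam=use_lam)
    dense = cov.dense()
    scale = np.abs(dense).max()
    assert np.allclose(cov.diagonal(), np.diag(dense), atol=1e-10 * scale)
    ns = cross1_op.n_targets
    for _ in range(100):
        v = rng.normal(size=ns)
        q_ref = float(v @ dense @ v)
        assert abs(cov.quadratic_form(v) - q_ref) <= 1e-8 * max(abs(q_ref), scale)
    if use_lam < 1.0:  # full-rank case only: lambda=1 is rank-deficient
        for _ in range(10):
            rhs = rng.normal(size=ns)
            y_ref = np.linalg.solve(dense, rhs)
            y = cov.solve(rhs)
            assert np.linalg.norm(y - y_ref) <= 1e-8 * np.linalg.norm(y_ref)


def test_quadratic_forms_are_nonnegative(cross1_op):
    rng = np.random.default_rng(9)
    scans = rng.normal(scale=0.01, size=(5, cross1_op.n_sources))
    factor = e.covariance_of_mean(scans)
    cov = e.propagate_covariance(cross1_op, factor,
                                 lam=e.shrinkage_intensity(factor))
    for _ in range(50):
        assert cov.quadratic_form(rng.normal(size=cross1_op.n_targets)) >= 0.0


def test_solve_refuses_rank_deficient_lambda1(cross1_op):
    rng = np.random.default_rng(10)
    scans = rng.normal(scale=0.01, size=(4, cross1_op.n_sources))
    cov = e.propagate_covariance(cross1_op, e.covariance_of_mean(scans), lam=1.0)
    with pytest.raises(np.linalg.LinAlgError):
        cov.solve(np.ones(cross1_op.n_targets))


def test_covariance_of_maps_contracts():
    maps = np.tile(np.arange(6.0), (4, 1))
    cov, lam = e.covariance_of_maps(maps)
    assert lam == 0.0
    assert np.allclose(cov.diagonal(), 0.0)
    s = np.array([1.0, 2.0, 3.0])
    d = np.array([0.1, -0.2, 0.05])
    cov2, _ = e.covariance_of_maps(np.stack([s + d, s - d]))
    assert np.allclose(cov2.diagonal(), d**2, atol=1e-15)


def test_voxelwise_uncertainty_sqrt_diagonal():
    cov = PropagatedCovariance(np.zeros((3, 1)), sparse.identity(3) * 4.0,
                               lam=0.0, K=2)
    assert np.allclose(e.voxelwise_uncertainty(cov), 2.0)
    bad = PropagatedCovariance(np.zeros((2, 1)),
                               sparse.diags([-1.0, 1.0]), lam=0.0, K=2)
    with pytest.raises(ValueError, match="negative variance"):
        e.voxelwise_uncertainty(bad)


def test_monte_carlo_propagation_oracle(cross1_op):
    """Propagated iid-noise variances match empirical variances of
    independently reconstructed maps."""
    rng = np.random.default_rng(11)
    s, n_mc = 0.02, 400
    np_, ns = cross1_op.n_sources, cross1_op.n_targets
    maps = np.stack([cross1_op.matrix @ rng.normal(scale=s, size=np_)
                     for _ in range(n_mc)])
    emp = maps.var(axis=0, ddof=1)
    rownorm2 = np.asarray(cross1_op.matrix.multiply(cross1_op.matrix).sum(axis=1)).ravel()
    pred = s**2 * rownorm2
    ratio = emp / pred
    se = np.sqrt(2.0 / (n_mc - 1))            # relative MC error of a variance
    assert abs(ratio.mean() - 1.0) < 3 * se   # averaged check
    assert np.all(np.abs(ratio - 1.0) < 6 * se)  # loose per-voxel bound
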