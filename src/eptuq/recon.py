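"""Helmholtz-EPT conductivity reconstruction from transceive phase.

Phase-based reconstruction divides the Savitzky–Golay Laplacian of the
transceive phase by ``2 omega mu0``.  The complete variant adds the
transmit-sensitivity correction ``2 grad|B1+| . grad(phi+) / (omega mu0 |B1+|)``
with ``phi+ = phi+- / 2``; the relative gradient ``grad|B1+| / |B1+|`` is
evaluated as the SG gradient of ``log|B1+|``, which is exact for log-linear
sensitivity profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import MU0, Volume
from .sg import LaplacianOperator, RoiMask, apply_operator, gradient_at_targets


@dataclass
class ConductivityMap:
    """Conductivity values (S/m) on the operator's target voxels."""

    values: np.ndarray
    operator: LaplacianOperator
    method: str                       # "phase_based" | "complete"
    condition: str | None = None
    scan_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.operator.n_targets,):
            raise ValueError("conductivity length does not match operator targets")


def demean_phase(scans: list[Volume], mask: RoiMask) -> list[Volume]:
    """Remove each scan's spatial mean over the ROI sphere.

    Constant phase offsets between scans carry no conductivity information
    (the Laplacian annihilates them) but would show up as spurious perfectly
    correlated components in the phase covariance.
    """
    if mask.n_members == 0:
        raise ValueError("empty ROI mask")
    out = []
    for v in scans:
        if v.shape != mask.grid_shape:
            raise ValueError("scan grid does not match the mask")
        m = mask.extract(v.values).mean()
        out.append(Volume(v.values - m, v.voxel_size, v.origin, v.scan_id))
    return out


def mean_phase(scans: list[Volume]) -> Volume:
    """Voxelwise mean of a set of co-registered scans."""
    if len(scans) == 0:
        raise ValueError("no scans given")
    ref = scans[0]
    for v in scans[1:]:
        if not v.same_grid(ref):
            raise ValueError("scans are not on the same grid")
    mean = np.mean([v.values for v in scans], axis=0)
    return Volume(mean, ref.voxel_size, ref.origin, scan_id="mean")


def _check_phase(phase: Volume, mask: RoiMask) -> None:
    vals = mask.extract(phase.values)
    if not np.all(np.isfinite(vals)):
        bad = mask.member_flat[~np.isfinite(vals)]
        raise ValueError(f"non-finite phase at ROI voxels (flat indices) {bad[:10]}")
    # wrap detector: adjacent ROI voxels should never jump by more than pi
    v, m = phase.values, mask.mask
    for ax in range(3):
        d = np.abs(np.diff(v, axis=ax))
        pair = np.logical_and(
            np.take(m, range(0, m.shape[ax] - 1), axis=ax),
            np.take(m, range(1, m.shape[ax]), axis=ax),
        )
        if np.any(d[pair] > np.pi):
            raise ValueError(
                "phase jump larger than pi between neighboring ROI voxels: "
                "the transceive phase appears wrapped; unwrap before reconstruction"
            )


def phase_based_sigma(
    phase: Volume, op: LaplacianOperator, condition: str | None = None
) -> ConductivityMap:
    """Phase-based Helmholtz-EPT: ``sigma = lap(phi+-) / (2 omega mu0)``."""
    _check_phase(phase, op.mask)
    p = op.mask.extract(phase.values)
    s = apply_operator(op, p)
    return ConductivityMap(s, op, "phase_based", condition, phase.scan_id)


def complete_sigma(
    phase: Volume,
    magnitude: Volume,
    op: LaplacianOperator,
    condition: str | None = None,
) -> ConductivityMap:
    """Complete Helmholtz-EPT from transceive phase and ``|B1+|^2`` volume.

    ``sigma = lap(phi+)/(omega mu0) + 2 grad|B1+| . grad(phi+) / (omega mu0 |B1+|)``
    with ``phi+ = phi+- / 2``; in terms of the acquired transceive phase the
    correction is ``grad(log|B1+|) . grad(phi+-) / (omega mu0)``.
    """
    if phase.shape != magnitude.shape:
        raise ValueError("phase and magnitude grids differ")
    mag_roi = op.mask.extract(magnitude.values)
    if np.any(mag_roi <= 0) or not np.all(np.isfinite(mag_roi)):
        raise ValueError("transmit magnitude must be positive and finite in the ROI")
    base = phase_based_sigma(phase, op, condition)
    # outside the ROI the magnitude may be zero or negative; those voxels carry
    # zero stencil weight but must not inject NaN into the correlation
    safe = np.where(magnitude.values > 0, magnitude.values, 1.0)
    log_b1 = 0.5 * np.log(safe)
    g_log = gradient_at_targets(op, log_b1)
    g_phi = gradient_at_targets(op, phase.values)
    correction = np.sum(g_log * g_phi, axis=1) / (op.omega * MU0)
    return ConductivityMap(base.values + correction, op, "complete",
                           condition, phase.scan_id)
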