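"""End-to-end repeatability / reproducibility analysis of a scan set.

Repeatability path: de-mean each phase scan over the analysis sphere, average
them voxel by voxel, reconstruct the mean phase, estimate the shrunken
covariance of the mean phase and propagate it through the operator.

Reproducibility path: reconstruct every repositioned scan on an analysis
sphere re-centered at that scan's phantom position (the spheres are exact
lattice translates, so maps are compared on matching regions of the
phantom), average the conductivity maps, and estimate the shrunken
covariance directly on the maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import covariance as cov_mod
from . import recon, stats
from .grid import Volume
from .sg import LaplacianOperator, assemble_operator, build_kernel, make_bp_mask
from .synthetic import SimulatedStudy


@dataclass
class StudySummary:
    """Everything the reporting stage needs from one (kernel, condition) run."""

    condition: str
    kernel_shape: str
    kernel_n: int
    n_sources: int                 # Np
    n_targets: int                 # Ns
    lam: float
    mean_map: recon.ConductivityMap
    covariance: cov_mod.PropagatedCovariance
    average: stats.AverageResult
    dispersion: stats.DispersionSummary
    dispersion_vs_uncertainty: dict


def _operator_for(study: SimulatedStudy, kernel_shape: str, n: int,
                  roi_radius: float, center: np.ndarray) -> LaplacianOperator:
    acq = study.acquisition
    kernel = build_kernel(kernel_shape, n, acq.voxel_size)
    mask = make_bp_mask(acq.grid_shape, acq.voxel_size, center, roi_radius)
    return assemble_operator(kernel, mask, acq.omega)


def run_repeatability(
    study: SimulatedStudy,
    kernel_shape: str = "sphere",
    n: int = 3,
    roi_radius: float = 0.03,
    sigma_exp: float | None = None,
    shrink: bool = True,
) -> StudySummary:
    if study.condition != "repeatability":
        raise ValueError("run_repeatability needs a repeatability study")
    center = study.per_scan_centers[0]
    op = _operator_for(study, kernel_shape, n, roi_radius, center)

    scans = recon.demean_phase(study.phase_volumes, op.mask)
    p_stack = np.stack([op.mask.extract(v.values) for v in scans])   # (K, Np)
    mean_vol = recon.mean_phase(scans)
    s_mean = recon.phase_based_sigma(mean_vol, op, condition="repeatability")

    factor = cov_mod.covariance_of_mean(p_stack)
    lam = cov_mod.shrinkage_intensity(factor) if shrink else 1.0
    sigma_cov = cov_mod.propagate_covariance(op, factor, lam=lam)
    return _summarize(study, s_mean, sigma_cov, lam, kernel_shape, n, sigma_exp)


def run_reproducibility(
    study: SimulatedStudy,
    kernel_shape: str = "sphere",
    n: int = 3,
    roi_radius: float = 0.03,
    sigma_exp: float | None = None,
    shrink: bool = True,
) -> StudySummary:
    if study.condition != "reproducibility":
        raise ValueError("run_reproducibility needs a reproducibility study")
    acq = study.acquisition
    h = acq.voxel_size
    base = study.per_scan_centers[0]
    op = _operator_for(study, kernel_shape, n, roi_radius, base)

    # every scan's sphere is a lattice translate of the first one
    maps = []
    for vol, center in zip(study.phase_volumes, study.per_scan_centers):
        shift = (center - base) / h
        ishift = np.rint(shift).astype(int)
        if not np.allclose(shift, ishift, atol=1e-6):
            raise ValueError(
                "phantom centers are not voxel-aligned; re-simulate with snapped offsets"
            )
        coords = op.mask.member_coords + ishift
        if np.any(coords < 0) or np.any(coords >= np.asarray(vol.shape)):
            raise ValueError("analysis sphere falls outside the grid for a scan")
        p = vol.values[coords[:, 0], coords[:, 1], coords[:, 2]]
        maps.append(op.matrix @ p)
    maps = np.stack(maps)                                            # (K, Ns)

    mean_values = maps.mean(axis=0)
    s_mean = recon.ConductivityMap(mean_values, op, "phase_based",
                                   condition="reproducibility", scan_id="mean")
    sigma_cov, lam = cov_mod.covariance_of_maps(maps, shrink=shrink)
    return _summarize(study, s_mean, sigma_cov, lam, kernel_shape, n, sigma_exp)


def _summarize(study, s_mean, sigma_cov, lam, kernel_shape, n, sigma_exp):
    if sigma_exp is None:
        sigma_exp = study.truth.sigma_true
    avg = stats.spatial_average(
        s_mean, sigma_cov, kernel=f"{kernel_shape} n={n}", condition=study.condition
    )
    disp = stats.boxplot_stats(s_mean, sigma_exp, sigma_cov)
    comparison = stats.dispersion_vs_uncertainty(s_mean, sigma_cov)
    op = s_mean.operator
    return StudySummary(
        condition=study.condition, kernel_shape=kernel_shape, kernel_n=n,
        n_sources=op.n_sources, n_targets=op.n_targets, lam=lam,
        mean_map=s_mean, covariance=sigma_cov, average=avg,
        dispersion=disp, dispersion_vs_uncertainty=comparison,
    )


def run_study(study: SimulatedStudy, **kwargs) -> StudySummary:
    """Dispatch on the study's condition tag."""
    if study.condition == "repeatability":
        return run_repeatability(study, **kwargs)
    return run_reproducibility(study, **kwargs)
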