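"""Readers and writers: NIfTI-1 volumes, YAML manifests, HDF5 exports.

Volumes are stored as NIfTI-1 with an affine that encodes the isotropic voxel
size (in mm, the NIfTI convention) and the grid origin as the translation
part.  Simulated studies are written one file per scan plus a YAML manifest
recording the condition, seeds and ground truth.  Operators and covariances
export to HDF5 for audit, with a JSON sidecar giving the headline uncertainty
in mS/m.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from .covariance import PropagatedCovariance, voxelwise_uncertainty
from .grid import Volume
from .sg import LaplacianOperator
from .synthetic import AcquisitionSpec, PhantomSpec, SimulatedStudy


class VolumeFormatError(ValueError):
    """Raised for unreadable, corrupt or unsupported volume files."""


def write_volume(vol: Volume, path: str | Path) -> Path:
    path = Path(path)
    affine = np.eye(4)
    affine[:3, :3] *= vol.voxel_size * 1e3       # NIfTI spatial units: mm
    affine[:3, 3] = vol.origin * 1e3
    img = nib.Nifti1Image(vol.values, affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, path)
    return path


def read_volume(path: str | Path) -> Volume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(path)
        values = np.asarray(img.get_fdata(), dtype=float)
        affine = img.affine
    except Exception as exc:  # corrupt header, wrong magic, truncated file
        raise VolumeFormatError(f"cannot read {path} as NIfTI-1: {exc}") from exc
    if values.ndim != 3:
        raise VolumeFormatError(f"{path}: expected a 3D volume, got shape {values.shape}")
    zooms = np.sqrt(np.sum(affine[:3, :3] ** 2, axis=0))
    if not np.allclose(zooms, zooms[0], rtol=1e-4):
        raise VolumeFormatError(
            f"{path}: anisotropic voxels {zooms} mm are not supported"
        )
    return Volume(values, float(zooms[0]) * 1e-3, origin=affine[:3, 3] * 1e-3,
                  scan_id=path.stem.split(".")[0])


def write_study(study: SimulatedStudy, out_dir: str | Path) -> Path:
    """One NIfTI per scan plus ``manifest.yaml`` with condition and truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []
    for k, vol in enumerate(study.phase_volumes):
        name = f"phase_{k:03d}.nii.gz"
        v = Volume(vol.values, vol.voxel_size, vol.origin, vol.scan_id)
        write_volume(v, out_dir / name)
        files.append(name)
    acq = study.acquisition
    manifest = {
        "condition": study.condition,
        "phase_files": files,
        "per_scan_centers_m": study.per_scan_centers.tolist(),
        "acquisition": {
            "grid_shape": list(acq.grid_shape),
            "voxel_size_m": acq.voxel_size,
            "larmor_frequency_hz": acq.larmor_frequency,
            "n_repetitions": acq.n_repetitions,
            "n_reproductions": acq.n_reproductions,
            "noise_sd_rad": acq.noise_sd,
            "artifact_amplitude_rad": acq.artifact_amplitude,
            "artifact_correlation_length_m": acq.artifact_correlation_length,
            "rng_seed": acq.rng_seed,
        },
        "truth": {
            "sigma_true_S_per_m": study.truth.sigma_true,
            "cylinder_radius_m": study.truth.cylinder_radius,
            "cylinder_length_m": study.truth.cylinder_length,
            "temperature_C": study.truth.temperature,
        },
    }
    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return out_dir


def read_study(in_dir: str | Path) -> SimulatedStudy:
    in_dir = Path(in_dir)
    with open(in_dir / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    a = manifest["acquisition"]
    acq = AcquisitionSpec(
        grid_shape=tuple(a["grid_shape"]), voxel_size=a["voxel_size_m"],
        larmor_frequency=a["larmor_frequency_hz"],
        n_repetitions=a["n_repetitions"], n_reproductions=a["n_reproductions"],
        noise_sd=a["noise_sd_rad"], artifact_amplitude=a["artifact_amplitude_rad"],
        artifact_correlation_length=a["artifact_correlation_length_m"],
        rng_seed=a["rng_seed"],
    )
    t = manifest["truth"]
    centers = np.asarray(manifest["per_scan_centers_m"], dtype=float)
    phantom = PhantomSpec(
        cylinder_radius=t["cylinder_radius_m"], cylinder_length=t["cylinder_length_m"],
        sigma_true=t["sigma_true_S_per_m"], temperature=t["temperature_C"],
        center=tuple(centers[0]),
    )
    vols = [read_volume(in_dir / f) for f in manifest["phase_files"]]
    return SimulatedStudy(vols, phantom, acq, manifest["condition"], centers)


def export_operator(op: LaplacianOperator, path: str | Path) -> Path:
    """CSR entries plus source/target voxel ids, for external audit."""
    path = Path(path)
    m = op.matrix
    with h5py.File(path, "w") as fh:
        fh.create_dataset("indptr", data=m.indptr)
        fh.create_dataset("indices", data=m.indices)
        fh.create_dataset("values", data=m.data)
        fh.create_dataset("target_flat", data=op.target_flat)
        fh.create_dataset("source_flat", data=op.source_flat)
        fh.attrs["kernel_shape"] = op.kernel.shape
        fh.attrs["kernel_n"] = op.kernel.n
        fh.attrs["voxel_size_m"] = op.kernel.voxel_size
        fh.attrs["omega_rad_per_s"] = op.omega
        fh.attrs["roi_radius_m"] = op.mask.radius
        fh.attrs["flat_order"] = "F (x fastest, z slowest)"
    return path


def export_covariance(cov: PropagatedCovariance, path: str | Path) -> Path:
    """Factor matrices, diagonal and lambda to HDF5 + JSON sidecar (mS/m)."""
    path = Path(path)
    sp = cov.sparse_part.tocsr()
    with h5py.File(path, "w") as fh:
        fh.create_dataset("low_rank_factor", data=cov.low_rank)
        fh.create_dataset("sparse_indptr", data=sp.indptr)
        fh.create_dataset("sparse_indices", data=sp.indices)
        fh.create_dataset("sparse_values", data=sp.data)
        fh.create_dataset("diagonal", data=cov.diagonal())
        fh.attrs["lambda"] = cov.lam
        fh.attrs["n_scans"] = cov.K
    sidecar = {
        "lambda": cov.lam,
        "n_scans": cov.K,
        "mean_voxel_uncertainty_mS_per_m":
            float(np.mean(voxelwise_uncertainty(cov))) * 1e3,
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return path


def write_conductivity_map(s_map, path_nifti: str | Path,
                           path_csv: str | Path | None = None) -> None:
    """NaN-padded NIfTI of a conductivity map plus an optional CSV table."""
    op = s_map.operator
    full = np.full(op.mask.grid_shape, np.nan)
    t = op.target_coords
    full[t[:, 0], t[:, 1], t[:, 2]] = s_map.values
    write_volume(Volume(full, op.kernel.voxel_size), path_nifti)
    if path_csv is not None:
        h = op.kernel.voxel_size
        import pandas as pd

        pd.DataFrame({
            "flat_index": op.target_flat,
            "x_m": (t[:, 0] + 0.5) * h,
            "y_m": (t[:, 1] + 0.5) * h,
            "z_m": (t[:, 2] + 0.5) * h,
            "sigma_S_per_m": s_map.values,
        }).to_csv(path_csv, index=False)
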