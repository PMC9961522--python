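"""Synthetic homogeneous-phantom studies with the statistics the analysis assumes.

The generator emulates a saline cylinder scanned at 3 T: the transceive phase
is constructed so that its Laplacian encodes a programmed conductivity exactly
(``phi = omega * mu0 * sigma / 3 * |r - c|^2`` plus optional harmonic terms
with zero Laplacian), on top of which two error sources are added:

* a smooth *artifact* field — Gaussian white noise filtered with an isotropic
  Gaussian of configurable correlation length — that is held fixed across
  repeated scans of an unmoved phantom but redrawn whenever the phantom is
  repositioned, mimicking systematic acquisition errors that look random in
  space but are repeatable in time;
* i.i.d. Gaussian per-voxel phase noise, fresh in every scan.

Repeated scans of the unmoved phantom ("repetitions") and scans with the
phantom displaced between acquisitions ("reproductions") are generated with
deterministic per-scan random streams derived from one master seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .grid import MU0, Volume, grid_center

#: Conductivity of the 64 mM NaCl solution at 128 MHz: 550 mS/m at 16 degC
#: rising linearly to 570 mS/m at 18 degC.
_T_LOW, _SIGMA_LOW = 16.0, 0.550
_T_HIGH, _SIGMA_HIGH = 18.0, 0.570


def temperature_to_conductivity(temperature_c: float) -> float:
    """Phantom conductivity (S/m) from room temperature (degC), linear law.

    Valid between 16 and 18 degC; outside that range the law is extrapolated
    linearly and a warning is emitted.
    """
    t = float(temperature_c)
    if not (_T_LOW <= t <= _T_HIGH):
        warnings.warn(
            f"temperature {t} degC outside the calibrated 16-18 degC range; "
            "extrapolating the linear law",
            stacklevel=2,
        )
    slope = (_SIGMA_HIGH - _SIGMA_LOW) / (_T_HIGH - _T_LOW)
    return _SIGMA_LOW + slope * (t - _T_LOW)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and true conductivity of the homogeneous cylindrical phantom."""

    cylinder_radius: float = 0.06     # m
    cylinder_length: float = 0.18     # m
    sigma_true: float = 0.560         # S/m
    temperature: float = 17.0         # degC
    center: tuple[float, float, float] | None = None  # m; None = grid center

    def __post_init__(self) -> None:
        if self.cylinder_radius <= 0 or self.cylinder_length <= 0:
            raise ValueError("cylinder dimensions must be positive")
        if self.sigma_true <= 0:
            raise ValueError("sigma_true must be positive")

    def resolve_center(self, acq: "AcquisitionSpec") -> np.ndarray:
        if self.center is not None:
            return np.asarray(self.center, dtype=float)
        return grid_center(acq.grid_shape, acq.voxel_size)


@dataclass(frozen=True)
class AcquisitionSpec:
    """Grid, frequency, scan counts and noise/artifact levels of a study.

    Defaults mirror the experimental conditions the package targets: a 2 mm
    isotropic grid at 3 T (128 MHz), 25 repetitions and 8 reproductions.
    The phase-noise standard deviation of 0.01 rad corresponds to a magnitude
    SNR of about 100; the artifact amplitude (0.02 rad) and correlation
    length (1 cm) are qualitative stand-ins for the smooth repeatable
    acquisition artifacts seen in practice.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size: float = 0.002           # m
    larmor_frequency: float = 128e6     # Hz
    n_repetitions: int = 25
    n_reproductions: int = 8
    noise_sd: float = 0.01              # rad
    artifact_amplitude: float = 0.02    # rad
    artifact_correlation_length: float = 0.01  # m
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.larmor_frequency <= 0:
            raise ValueError("larmor_frequency must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.artifact_amplitude < 0:
            raise ValueError("artifact_amplitude must be non-negative")
        if self.n_repetitions < 1 or self.n_reproductions < 1:
            raise ValueError("scan counts must be at least 1")

    @property
    def omega(self) -> float:
        """Angular Larmor frequency (rad/s)."""
        return 2.0 * np.pi * self.larmor_frequency


@dataclass
class SimulatedStudy:
    """A set of simulated scans plus the ground truth that produced them."""

    phase_volumes: list[Volume]
    truth: PhantomSpec
    acquisition: AcquisitionSpec
    condition: str                       # "repeatability" | "reproducibility"
    per_scan_centers: np.ndarray         # (K, 3) m
    magnitude_volumes: list[Volume] | None = None

    def __post_init__(self) -> None:
        if self.condition not in ("repeatability", "reproducibility"):
            raise ValueError(f"unknown condition {self.condition!r}")
        ref = self.phase_volumes[0]
        if not all(v.same_grid(ref) for v in self.phase_volumes):
            raise ValueError("all scans must share one grid")
        self.per_scan_centers = np.atleast_2d(np.asarray(self.per_scan_centers, float))
        if self.condition == "repeatability":
            if not np.allclose(self.per_scan_centers, self.per_scan_centers[0]):
                raise ValueError("repeatability scans must share one phantom center")

    @property
    def n_scans(self) -> int:
        return len(self.phase_volumes)


def _check_roi_fits(acq: AcquisitionSpec, phantom: PhantomSpec,
                    center: np.ndarray, roi_radius: float) -> None:
    extent = np.asarray(acq.grid_shape) * acq.voxel_size
    if np.any(center - roi_radius < 0) or np.any(center + roi_radius > extent):
        raise ValueError(
            f"grid of extent {extent} m is too small to contain the analysis sphere "
            f"(radius {roi_radius} m) at center {center} m"
        )
    if roi_radius > phantom.cylinder_radius or 2 * roi_radius > phantom.cylinder_length:
        raise ValueError("analysis sphere does not fit inside the phantom cylinder")


def make_true_phase(
    acq: AcquisitionSpec,
    phantom: PhantomSpec,
    harmonic: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray] | None = None,
    roi_radius: float = 0.03,
    center: np.ndarray | None = None,
) -> Volume:
    """Noise-free transceive phase whose Laplacian encodes ``sigma_true``.

    ``phi(r) = (omega mu0 sigma / 3) |r - c|^2 (+ harmonic(x, y, z))`` so that
    ``lap(phi) = 2 omega mu0 sigma`` at every voxel; the optional ``harmonic``
    callable receives phantom-centered coordinates and must have zero
    Laplacian for the encoding to stay exact.
    """
    c = phantom.resolve_center(acq) if center is None else np.asarray(center, float)
    _check_roi_fits(acq, phantom, c, roi_radius)
    vol = Volume(np.zeros(acq.grid_shape), acq.voxel_size)
    gx, gy, gz = vol.coordinate_grids()
    x, y, z = gx - c[0], gy - c[1], gz - c[2]
    coeff = acq.omega * MU0 * phantom.sigma_true / 3.0
    phi = coeff * (x**2 + y**2 + z**2)
    if harmonic is not None:
        phi = phi + harmonic(x, y, z)
    return Volume(phi, acq.voxel_size, scan_id="truth")


def make_artifact_field(
    acq: AcquisitionSpec,
    seed: int | np.random.SeedSequence | None = None,
    amplitude: float | None = None,
    correlation_length: float | None = None,
) -> np.ndarray:
    """Smooth zero-mean artifact field (rad) with the given spatial scale.

    Gaussian white noise filtered with an isotropic Gaussian of standard
    deviation ``correlation_length``; re-centered to zero mean and rescaled so
    the grid-wide standard deviation equals ``amplitude`` exactly.
    Deterministic given the seed.
    """
    amplitude = acq.artifact_amplitude if amplitude is None else float(amplitude)
    cl = (acq.artifact_correlation_length if correlation_length is None
          else float(correlation_length))
    if amplitude < 0:
        raise ValueError("artifact amplitude must be non-negative")
    if amplitude == 0.0:
        return np.zeros(acq.grid_shape)
    if cl < acq.voxel_size:
        warnings.warn(
            "artifact correlation length below the voxel size; the field "
            "degenerates to white noise",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(acq.grid_shape)
    smooth = ndimage.gaussian_filter(white, sigma=cl / acq.voxel_size, mode="reflect")
    smooth -= smooth.mean()
    sd = smooth.std()
    if sd == 0.0:  # pathological single-voxel grids
        return np.zeros(acq.grid_shape)
    return smooth * (amplitude / sd)


def _study_streams(acq: AcquisitionSpec, n: int) -> tuple[list, list]:
    """Per-scan (artifact, noise) seed sequences derived from the master seed."""
    ss = np.random.SeedSequence(acq.rng_seed)
    children = ss.spawn(2 * n)
    return children[:n], children[n:]


def simulate_repetitions(
    acq: AcquisitionSpec,
    phantom: PhantomSpec,
    harmonic: Callable | None = None,
    roi_radius: float = 0.03,
) -> SimulatedStudy:
    """Repeated scans of an unmoved phantom: one shared artifact, fresh noise."""
    center = phantom.resolve_center(acq)
    truth = make_true_phase(acq, phantom, harmonic, roi_radius, center)
    art_streams, noise_streams = _study_streams(acq, acq.n_repetitions)
    artifact = make_artifact_field(acq, seed=art_streams[0])
    scans = []
    for k in range(acq.n_repetitions):
        rng = np.random.default_rng(noise_streams[k])
        noise = (rng.standard_normal(acq.grid_shape) * acq.noise_sd
                 if acq.noise_sd > 0 else 0.0)
        scans.append(Volume(truth.values + artifact + noise, acq.voxel_size,
                            scan_id=f"rep{k:02d}"))
    centers = np.tile(center, (acq.n_repetitions, 1))
    return SimulatedStudy(scans, phantom, acq, "repeatability", centers)


def default_reproduction_offsets(acq: AcquisitionSpec,
                                 spacing: float = 0.06) -> np.ndarray:
    """Ring of ``n_reproductions`` in-plane offsets with successive centers
    ``spacing`` apart (chord length), snapped to the voxel grid."""
    n = acq.n_reproductions
    radius = spacing / (2.0 * np.sin(np.pi / n)) if n > 1 else 0.0
    angles = 2.0 * np.pi * np.arange(n) / max(n, 1)
    offs = np.stack([radius * np.cos(angles), radius * np.sin(angles),
                     np.zeros(n)], axis=1)
    return np.round(offs / acq.voxel_size) * acq.voxel_size


def simulate_reproductions(
    acq: AcquisitionSpec,
    phantom: PhantomSpec,
    offsets: Sequence | None = None,
    harmonic: Callable | None = None,
    roi_radius: float = 0.03,
) -> SimulatedStudy:
    """Scans with the phantom repositioned: fresh artifact and noise per scan.

    ``offsets`` (m) displace the phantom center scan by scan; they are snapped
    to whole voxels so the analysis spheres of all scans are exact lattice
    translates of each other.  By default the phantom visits a ring of
    positions with successive centers 6 cm apart.
    """
    if offsets is None:
        offsets = default_reproduction_offsets(acq)
    offsets = np.atleast_2d(np.asarray(offsets, dtype=float))
    if len(offsets) != acq.n_reproductions:
        raise ValueError(
            f"got {len(offsets)} offsets for n_reproductions={acq.n_reproductions}"
        )
    offsets = np.round(offsets / acq.voxel_size) * acq.voxel_size
    base = phantom.resolve_center(acq)
    art_streams, noise_streams = _study_streams(acq, acq.n_reproductions)
    scans, centers = [], []
    for k, off in enumerate(offsets):
        center = base + off
        truth = make_true_phase(acq, phantom, harmonic, roi_radius, center)
        artifact = make_artifact_field(acq, seed=art_streams[k])
        rng = np.random.default_rng(noise_streams[k])
        noise = (rng.standard_normal(acq.grid_shape) * acq.noise_sd
                 if acq.noise_sd > 0 else 0.0)
        scans.append(Volume(truth.values + artifact + noise, acq.voxel_size,
                            scan_id=f"repro{k}"))
        centers.append(center)
    return SimulatedStudy(scans, phantom, acq, "reproducibility", np.array(centers))


def make_b1_magnitude(
    acq: AcquisitionSpec,
    base: float = 1.0,
    gradient: Sequence[float] = (0.0, 0.0, 0.0),
    center: np.ndarray | None = None,
) -> Volume:
    """Synthetic ``|B1+|^2`` proxy volume: ``(base * exp(g . (r - c)))^2``.

    Log-linear by construction, so the relative transmit-sensitivity gradient
    ``grad|B1+| / |B1+|`` equals ``g`` exactly everywhere.
    """
    if base <= 0:
        raise ValueError("base magnitude must be positive")
    g = np.asarray(gradient, dtype=float)
    vol = Volume(np.zeros(acq.grid_shape), acq.voxel_size)
    if center is None:
        center = grid_center(acq.grid_shape, acq.voxel_size)
    gx, gy, gz = vol.coordinate_grids()
    expo = g[0] * (gx - center[0]) + g[1] * (gy - center[1]) + g[2] * (gz - center[2])
    mag = (base * np.exp(expo)) ** 2
    return Volume(mag, acq.voxel_size, scan_id="b1sq")
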