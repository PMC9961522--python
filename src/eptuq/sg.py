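"""3D Savitzky–Golay differential kernels and the sparse reconstruction operator.

The discrete Laplacian that drives phase-based Helmholtz EPT is obtained by
fitting, in the least-squares sense, a quadratic polynomial (a paraboloid) to
the phase samples inside a small kernel centered on each voxel, and evaluating
the Laplacian of the fit analytically.  Three kernel shapes are supported —
a cross, a voxelized sphere and a cube — each parameterized by the half-width
``n`` of the bounding cube (edge ``2n + 1`` voxels).

The resulting linear functional is assembled into a sparse operator ``A``
mapping the ``Np`` phase samples inside a spherical region of interest to the
``Ns`` voxels whose kernel lies entirely inside that region, scaled by
``1 / (2 * omega * mu0)`` so that ``s = A p`` is a conductivity in S/m.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse

from .grid import MU0, flat_indices, unflatten, voxel_centers_1d

logger = logging.getLogger(__name__)

KERNEL_SHAPES = ("cross", "sphere", "cube")

# Monomial exponents of the local quadratic model.  The cross kernel samples
# only on the coordinate axes, where every mixed monomial vanishes
# identically, so the three cross terms must be dropped to keep the design
# matrix full rank.
_BASIS_FULL = [
    (0, 0, 0),
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (2, 0, 0), (0, 2, 0), (0, 0, 2),
    (1, 1, 0), (1, 0, 1), (0, 1, 1),
]
_BASIS_AXIAL = _BASIS_FULL[:7]


@dataclass(frozen=True)
class Kernel:
    """A symmetric set of integer voxel offsets around the origin."""

    shape: str
    n: int
    voxel_size: float
    offsets: np.ndarray = field(repr=False)

    @property
    def size(self) -> int:
        return len(self.offsets)

    @property
    def half_width(self) -> int:
        """Half the edge of the bounding cube, in voxels."""
        return int(np.max(np.abs(self.offsets)))


@dataclass(frozen=True)
class SGWeights:
    """Per-offset weights of the fitted Laplacian and gradient functionals."""

    laplacian: np.ndarray  # (m,), units m^-2
    gradient: np.ndarray   # (m, 3), units m^-1


def build_kernel(shape: str, n: int, voxel_size: float) -> Kernel:
    """Enumerate the offsets of a cross / sphere / cube kernel of half-width n."""
    if shape not in KERNEL_SHAPES:
        raise ValueError(f"unknown kernel shape {shape!r}; expected one of {KERNEL_SHAPES}")
    if n < 1:
        raise ValueError("kernel half-width n must be >= 1")
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    if shape == "cross":
        offs = [(0, 0, 0)]
        for k in range(1, n + 1):
            offs += [(k, 0, 0), (-k, 0, 0), (0, k, 0), (0, -k, 0), (0, 0, k), (0, 0, -k)]
        offsets = np.array(offs, dtype=int)
    else:
        rng = range(-n, n + 1)
        cube = np.array(list(itertools.product(rng, rng, rng)), dtype=int)
        if shape == "cube":
            offsets = cube
        else:  # sphere: all lattice offsets with squared norm <= n^2
            offsets = cube[np.sum(cube * cube, axis=1) <= n * n]
    # deterministic ordering: lexicographic in (z, y, x)
    order = np.lexsort((offsets[:, 0], offsets[:, 1], offsets[:, 2]))
    offsets = offsets[order]
    offsets.setflags(write=False)
    return Kernel(shape=shape, n=n, voxel_size=voxel_size, offsets=offsets)


def sg_fit_weights(kernel: Kernel) -> SGWeights:
    """Weights of the least-squares paraboloid fit on the kernel support.

    The design matrix is evaluated in voxel units for conditioning; physical
    scaling by the voxel size is applied afterwards.  The Laplacian functional
    is ``2 (a200 + a020 + a002)`` and the gradient ``(a100, a010, a001)`` of
    the fitted coefficients, hence both are exact on quadratic fields.
    """
    # an axis-only support (cross at any n, sphere at n=1) samples every mixed
    # monomial at zero, so the cross terms must be dropped to keep full rank
    axis_only = bool(np.all(np.sum(kernel.offsets != 0, axis=1) <= 1))
    basis = _BASIS_AXIAL if axis_only else _BASIS_FULL
    if kernel.size < len(basis):
        raise ValueError(
            f"kernel has {kernel.size} points but the quadratic fit needs at least "
            f"{len(basis)}; reduce the basis or enlarge the kernel"
        )
    x = kernel.offsets.astype(float)
    design = np.column_stack(
        [x[:, 0] ** px * x[:, 1] ** py * x[:, 2] ** pz for (px, py, pz) in basis]
    )
    if np.linalg.matrix_rank(design) < len(basis):
        raise ValueError(
            "rank-deficient Savitzky-Golay design matrix: the kernel support cannot "
            "determine all quadratic coefficients; reduce the polynomial basis"
        )
    # rows of the pseudo-inverse are the linear functionals extracting each
    # polynomial coefficient from the samples
    pinv = np.linalg.pinv(design)
    h = kernel.voxel_size
    i = {b: k for k, b in enumerate(basis)}
    lap = 2.0 * (pinv[i[(2, 0, 0)]] + pinv[i[(0, 2, 0)]] + pinv[i[(0, 0, 2)]]) / h**2
    grad = np.stack(
        [pinv[i[(1, 0, 0)]], pinv[i[(0, 1, 0)]], pinv[i[(0, 0, 1)]]], axis=1
    ) / h
    return SGWeights(laplacian=lap, gradient=grad)


@dataclass
class RoiMask:
    """Spherical region of interest Bp on the voxel grid.

    Membership uses the voxel-center convention: a voxel belongs to the ROI
    when its center lies within ``radius`` of ``center``.  ``member_flat`` and
    ``member_coords`` are ordered by ascending Fortran flat index.
    """

    mask: np.ndarray          # (nx, ny, nz) bool
    voxel_size: float
    center: np.ndarray        # (3,) m
    radius: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.center = np.asarray(self.center, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        flat = np.flatnonzero(self.mask.ravel(order="F"))
        if flat.size == 0:
            raise ValueError("ROI mask is empty")
        self.member_flat = flat
        self.member_coords = unflatten(flat, self.mask.shape)

    @property
    def n_members(self) -> int:
        return int(self.member_flat.size)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.mask.shape  # type: ignore[return-value]

    def extract(self, values: np.ndarray) -> np.ndarray:
        """Gather a volume's values on the ROI members (flat-index order)."""
        c = self.member_coords
        return np.asarray(values)[c[:, 0], c[:, 1], c[:, 2]]


def make_bp_mask(
    grid_shape: tuple[int, int, int],
    voxel_size: float,
    center: np.ndarray,
    radius: float,
    origin: np.ndarray | None = None,
) -> RoiMask:
    """Spherical analysis mask of the given radius (m) around ``center`` (m)."""
    if radius <= 0:
        raise ValueError("ROI radius must be positive")
    origin = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)
    center = np.asarray(center, dtype=float)
    extent = np.asarray(grid_shape) * voxel_size
    if np.any(center - radius < origin) or np.any(center + radius > origin + extent):
        raise ValueError(
            f"ROI sphere (center {center}, radius {radius}) does not fit inside the "
            f"grid of extent {extent}"
        )
    axes = [
        voxel_centers_1d(n, voxel_size, o) - c
        for n, o, c in zip(grid_shape, origin, center)
    ]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij", sparse=True)
    mask = gx**2 + gy**2 + gz**2 <= radius**2
    roi = RoiMask(mask=mask, voxel_size=voxel_size, center=center,
                  radius=radius, origin=origin)
    logger.info(
        "ROI sphere radius %.4f m, voxel %.4f m: Np=%d members "
        "(voxel-center-within-radius convention)",
        radius, voxel_size, roi.n_members,
    )
    return roi


@dataclass
class LaplacianOperator:
    """Sparse operator ``A`` with ``s = A p`` the conductivity map (S/m).

    Rows correspond to target voxels (kernel entirely inside the ROI), columns
    to the ROI members; entries are the Savitzky–Golay Laplacian weights
    scaled by ``1 / (2 omega mu0)``.
    """

    kernel: Kernel
    mask: RoiMask
    omega: float
    weights: SGWeights
    matrix: sparse.csr_matrix
    target_flat: np.ndarray
    target_coords: np.ndarray

    @property
    def n_sources(self) -> int:
        return self.mask.n_members

    @property
    def n_targets(self) -> int:
        return int(self.target_flat.size)

    @property
    def source_flat(self) -> np.ndarray:
        return self.mask.member_flat

    @property
    def scale(self) -> float:
        return 1.0 / (2.0 * self.omega * MU0)


def assemble_operator(kernel: Kernel, mask: RoiMask, omega: float) -> LaplacianOperator:
    """Build the sparse phase-to-conductivity operator on the ROI.

    A voxel is a reconstruction target only when every kernel offset lands on
    an ROI member, so no Laplacian is ever estimated across the ROI boundary.
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    if not np.isclose(kernel.voxel_size, mask.voxel_size):
        raise ValueError("kernel and mask voxel sizes differ")
    weights = sg_fit_weights(kernel)
    shape = mask.grid_shape
    coords = mask.member_coords           # (Np, 3)
    offsets = kernel.offsets              # (m, 3)

    padded = np.zeros(tuple(s + 2 * kernel.half_width for s in shape), dtype=bool)
    hw = kernel.half_width
    padded[hw:hw + shape[0], hw:hw + shape[1], hw:hw + shape[2]] = mask.mask
    pc = coords + hw
    valid = np.ones(len(coords), dtype=bool)
    for off in offsets:
        q = pc + off
        valid &= padded[q[:, 0], q[:, 1], q[:, 2]]
    if not np.any(valid):
        raise ValueError(
            "no voxel has its full kernel inside the ROI; the kernel is too large "
            "for this mask"
        )
    tcoords = coords[valid]
    tflat = mask.member_flat[valid]       # already in ascending flat order

    pos = np.full(int(np.prod(shape)), -1, dtype=np.int64)
    pos[mask.member_flat] = np.arange(mask.n_members)
    n_t, m = len(tcoords), kernel.size
    cols = np.empty((n_t, m), dtype=np.int64)
    for j, off in enumerate(offsets):
        cols[:, j] = pos[flat_indices(tcoords + off, shape)]
    scale = 1.0 / (2.0 * omega * MU0)
    data = np.broadcast_to(weights.laplacian * scale, (n_t, m))
    rows = np.repeat(np.arange(n_t), m)
    matrix = sparse.csr_matrix(
        (data.ravel(), (rows, cols.ravel())), shape=(n_t, mask.n_members)
    )
    logger.info("operator %s n=%d: Np=%d, Ns=%d", kernel.shape, kernel.n,
                mask.n_members, n_t)
    return LaplacianOperator(
        kernel=kernel, mask=mask, omega=omega, weights=weights, matrix=matrix,
        target_flat=tflat, target_coords=tcoords,
    )


def apply_operator(op: LaplacianOperator, p: np.ndarray) -> np.ndarray:
    """Explicit sparse product ``s = A p`` on a phase vector of length Np."""
    p = np.asarray(p, dtype=float)
    if p.shape != (op.n_sources,):
        raise ValueError(
            f"phase vector has length {p.shape}, expected ({op.n_sources},)"
        )
    return op.matrix @ p


def _stencil_array(kernel: Kernel, weights: np.ndarray) -> np.ndarray:
    w = kernel.half_width
    st = np.zeros((2 * w + 1,) * 3)
    idx = kernel.offsets + w
    st[idx[:, 0], idx[:, 1], idx[:, 2]] = weights
    return st


def apply_moving_window(op: LaplacianOperator, volume_values: np.ndarray) -> np.ndarray:
    """Matrix-free evaluation of ``A p`` by correlating the full volume.

    Agrees with :func:`apply_operator` to machine precision; kept as an
    independent code path for cross-checking and for large volumes where the
    gather into a phase vector is not wanted.
    """
    st = _stencil_array(op.kernel, op.weights.laplacian)
    lap = ndimage.correlate(np.asarray(volume_values, dtype=float), st, mode="constant")
    t = op.target_coords
    return lap[t[:, 0], t[:, 1], t[:, 2]] * op.scale


def gradient_at_targets(op: LaplacianOperator, volume_values: np.ndarray) -> np.ndarray:
    """SG gradient estimates at the operator's target voxels, shape (Ns, 3)."""
    values = np.asarray(volume_values, dtype=float)
    t = op.target_coords
    out = np.empty((len(t), 3))
    for ax in range(3):
        st = _stencil_array(op.kernel, op.weights.gradient[:, ax])
        g = ndimage.correlate(values, st, mode="constant")
        out[:, ax] = g[t[:, 0], t[:, 1], t[:, 2]]
    return out
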