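import numpy as np
import pytest

import eptuq as e


@pytest.fixture(scope="session")
def small_acq():
    """Fast grid: 24^3 at 2 mm, 5 repetitions, 1 cm analysis sphere fits."""
    return e.AcquisitionSpec(
        grid_shape=(24, 24, 24), voxel_size=0.002, n_repetitions=5,
        n_reproductions=4, noise_sd=0.005, artifact_amplitude=0.01,
        rng_seed=0,
    )


@pytest.fixture(scope="session")
def phantom():
    return e.PhantomSpec()


@pytest.fixture(scope="session")
def small_mask(small_acq, phantom):
    center = phantom.resolve_center(small_acq)
    return e.make_bp_mask(small_acq.grid_shape, small_acq.voxel_size, center, 0.012)


@pytest.fixture(scope="session")
def cross1_op(small_acq, small_mask):
    kernel = e.build_kernel("cross", 1, small_acq.voxel_size)
    return e.assemble_operator(kernel, small_mask, small_acq.omega)


@pytest.fixture(scope="session")
def quad_phase(small_acq, phantom):
    """Noise-free phase encoding sigma_true = 0.56 S/m."""
    return e.make_true_phase(small_acq, phantom, roi_radius=0.012)
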