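import numpy as np
import pytest

from radgroup.fixtures import PhantomSpec, TableSpec, make_phantom
from radgroup.imaging import BinaryMask


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Two-compartment ellipsoid, no noise: high/low split is exact."""
    return make_phantom(PhantomSpec(noise_sd_hu=0.0, seed=0))


@pytest.fixture(scope="session")
def noisy_phantom():
    return make_phantom(PhantomSpec(noise_sd_hu=10.0, seed=1))


def ball_mask(radius_mm: float, spacing=(1.0, 1.0, 1.0), pad: int = 2) -> BinaryMask:
    """Digital ball: voxel centres within radius_mm of the centre."""
    spacing = np.asarray(spacing, dtype=float)
    half = np.ceil(radius_mm / spacing).astype(int) + pad
    shape = 2 * half + 1
    ax = [(np.arange(n) - h) * s for n, h, s in zip(shape, half, spacing)]
    xx, yy, zz = np.meshgrid(*ax, indexing="ij")
    values = xx**2 + yy**2 + zz**2 <= radius_mm**2
    return BinaryMask(values, tuple(spacing))


@pytest.fixture(scope="session")
def small_table_spec():
    """Compact block-correlated table for fast modeling tests."""
    return TableSpec(
        n_samples=100, n_shape=4, n_firstorder=4, n_texture=6,
        informative_group="firstorder", effect=1.2, seed=3,
    )
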