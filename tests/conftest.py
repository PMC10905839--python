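import numpy as np
import pytest

from craniowrap.grids import BinaryMask
from craniowrap.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_spec():
    """Coarse, fast phantom (1.6 mm voxels, 75^3) for geometry tests."""
    return PhantomSpec(seed=3, spacing_mm=1.6, noise_sigma=0.0,
                       bias_amplitude=0.0, anatomy_jitter=0.0)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def ball_mask():
    """Digital ball, radius 20 mm, 1 mm isotropic voxels."""
    n = 64
    ax = np.arange(n, dtype=float)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    c = 31.5
    return BinaryMask(data=(X - c) ** 2 + (Y - c) ** 2 + (Z - c) ** 2 <= 400.0,
                      spacing=(1.0, 1.0, 1.0)), np.array([c, c, c]), 20.0
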