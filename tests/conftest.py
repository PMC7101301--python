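import numpy as np
import pytest

from voxdose import (PhantomSpec, Structure, VoxelGrid, build_phantom,
                     load_nuclide)


@pytest.fixture(scope="session")
def nuclide():
    return load_nuclide()


@pytest.fixture()
def small_grid():
    return VoxelGrid(dims=(24, 24, 24))


@pytest.fixture()
def two_lesion_phantom(small_grid):
    """Phantom with a kidney-like organ and two lesions, washout per structure."""
    c = 4.79 * 11.5  # grid center, mm
    structures = [
        Structure(name="kidney_l", category="kidney",
                  center_mm=(c - 25, c, c), radii_mm=(18, 14, 14),
                  a0_kbq_ml=60.0, tau_h=90.0),
        Structure(name="lesion_1", category="liver",
                  center_mm=(c + 25, c + 10, c), radii_mm=(12, 12, 12),
                  a0_kbq_ml=150.0, tau_h=70.0),
        Structure(name="lesion_2", category="lymph_node",
                  center_mm=(c + 20, c - 25, c + 10), radii_mm=(8, 8, 8),
                  a0_kbq_ml=220.0, tau_h=45.0),
    ]
    return build_phantom(PhantomSpec(grid=small_grid, structures=structures))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
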