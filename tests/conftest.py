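import numpy as np
import pytest

from muquant.grids import MuMap, VoxelGrid
from muquant.mumap import default_bilinear_model
from muquant.physics import load_material_registry


@pytest.fixture(scope="session")
def registry():
    return load_material_registry()


@pytest.fixture(scope="session")
def bilinear():
    return default_bilinear_model()


@pytest.fixture()
def uniform_mu():
    """Uniform mu = 0.1355 cm^-1 slab, 240 x 80 x 6 mm at 2 mm voxels."""
    grid = VoxelGrid((120, 40, 3), (2.0, 2.0, 2.0), (0.0, 0.0, 0.0))
    return MuMap(grid, np.full(grid.shape, 0.1355))


@pytest.fixture()
def disk_mu():
    """Uniform disk of radius 100 mm, mu = 0.1355 cm^-1, on a 2 mm grid."""
    grid = VoxelGrid((121, 121, 3), (2.0, 2.0, 2.0), (-120.0, -120.0, 0.0))
    x, y, z = grid.center_mesh()
    values = np.where(x**2 + y**2 <= 100.0**2, 0.1355, 0.0) * np.ones_like(z)
    return MuMap(grid, values)
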