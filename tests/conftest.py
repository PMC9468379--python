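import numpy as np
import pytest

from contourqa import ImageGrid, StructureMask, StructureRecipe, make_structure


@pytest.fixture
def iso_grid():
    """1 mm isotropic grid big enough for r<=20 mm spheres at its center."""
    return ImageGrid(origin=(0, 0, 0), spacing=(1, 1, 1), shape=(45, 45, 45))


@pytest.fixture
def ct_grid():
    """Anisotropic grid mimicking the scan protocol: 1.17 mm in-plane, 7.5 mm slices."""
    return ImageGrid(origin=(0, 0, 0), spacing=(1.17, 1.17, 7.5), shape=(48, 48, 16))


def sphere_mask(grid, radius, center=None, name="sphere"):
    if center is None:
        center = tuple(
            grid.origin[i] + grid.spacing[i] * (grid.shape[i] - 1) / 2.0
            for i in range(3)
        )
    return make_structure(
        StructureRecipe(name=name, shape="sphere", center=center, radii=(radius,)),
        grid,
    )


def random_blob(grid, seed, p=0.5):
    """A random but reproducible non-empty mask (for property tests)."""
    rng = np.random.default_rng(seed)
    data = rng.random(grid.shape) < p
    if not data.any():
        data[tuple(s // 2 for s in grid.shape)] = True
    return StructureMask(name=f"blob{seed}", grid=grid, data=data)
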