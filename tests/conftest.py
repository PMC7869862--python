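import numpy as np
import pytest

from voxcyto.io_formats import LabelMap, VoxelGrid
from voxcyto.synthgen import (
    CellSpec,
    DepositSpec,
    GlomeruliSpec,
    NoiseSpec,
    PhantomSpec,
    VesselSpec,
)


@pytest.fixture
def small_grid():
    rng = np.random.default_rng(7)
    data = rng.uniform(0, 100, size=(2, 8, 16, 16)).astype(np.float32)
    return VoxelGrid(data, (1.0, 0.5, 0.5), ["cd31", "mhc2"])


@pytest.fixture
def sphere_labelmap():
    """Solid digitised sphere r=10 µm at the centre of a 1 µm isotropic grid."""

    def make(radius_um=10.0, shape=(28, 28, 28), voxel=(1.0, 1.0, 1.0)):
        z, y, x = np.ogrid[: shape[0], : shape[1], : shape[2]]
        center = [(s / 2) * v for s, v in zip(shape, voxel)]
        d2 = (
            ((z + 0.5) * voxel[0] - center[0]) ** 2
            + ((y + 0.5) * voxel[1] - center[1]) ** 2
            + ((x + 0.5) * voxel[2] - center[2]) ** 2
        )
        labels = (d2 <= radius_um**2).astype(np.int32)
        return LabelMap(labels, voxel, "sphere")

    return make


@pytest.fixture
def tiny_phantom_spec():
    """A fast, small phantom with every object class present."""
    return PhantomSpec(
        shape_voxels=(40, 96, 160),
        voxel_size_um=(1.0, 0.5, 0.5),
        glomeruli=GlomeruliSpec(count=2, radius_um=(7.0, 0.5), shell_thickness_um=2.0,
                                region_x_um=(8.0, 22.0)),
        vessels=VesselSpec(count=1, radius_um=2.5, waypoints=2),
        cells=CellSpec(
            count=20,
            radius_um=(2.2, 0.2),
            population_fractions={"within": 0.2, "surrounding": 0.3, "peripheral": 0.5},
        ),
        deposits=DepositSpec(fraction_of_glomeruli_with_deposits=0.5,
                             per_glomerulus_count=2, radius_um=1.2),
        noise=NoiseSpec(background_level=20.0, gaussian_sd=3.0, poisson=False),
        seed=123,
    )
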