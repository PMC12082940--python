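import numpy as np
import pytest

from bronchodose import anatomy as ana
from bronchodose import synthetic as synth
from bronchodose.grids import ScalarVolume, StructureMask, VoxelGrid


@pytest.fixture
def unit_grid():
    """1-mm isotropic 11³ grid with origin at zero."""
    return VoxelGrid((0.0, 0.0, 0.0), (1.0, 1.0, 1.0), (11, 11, 11))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dose(grid: VoxelGrid, rng, low=0.0, high=120.0):
    from bronchodose.dosimetry import DoseStudy

    vals = rng.uniform(low, high, size=grid.dims)
    return DoseStudy(ScalarVolume(grid, vals, kind="dose"))


def random_mask(grid: VoxelGrid, rng, p=0.3) -> StructureMask:
    m = rng.random(grid.dims) < p
    if not m.any():
        m[tuple(d // 2 for d in grid.dims)] = True
    return StructureMask(grid, m, "random")


@pytest.fixture(scope="session")
def phantom64():
    """Session phantom at the study resolution (64³, 3 mm)."""
    spec = synth.PhantomSpec(dims=(64, 64, 64), spacing_mm=3.0)
    return synth.make_phantom(spec)


@pytest.fixture(scope="session")
def anatomy64(phantom64):
    ct, prim, _ = phantom64
    return ana.derive_anatomy(ct, prim["CBT"], prim["CTV"])


@pytest.fixture(scope="session")
def phantom2mm():
    """Finer phantom (64³, 2 mm) for sub-voxel motion-recovery checks."""
    spec = synth.PhantomSpec(dims=(64, 64, 64), spacing_mm=2.0)
    return synth.make_phantom(spec)
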