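import numpy as np
import pytest

from voxelfe import (BCSpec, DensityVolume, PhantomSpec, SegmentationConfig,
                     assign_stm, build_mesh, generate_phantom, segment)


@pytest.fixture(scope="session")
def study_spec() -> PhantomSpec:
    """The 32x32x64 phantom used throughout the heavier tests."""
    return PhantomSpec(grid_shape=(32, 32), n_slices=64)


@pytest.fixture(scope="session")
def phantom_vol(study_spec) -> DensityVolume:
    return generate_phantom(study_spec)


@pytest.fixture(scope="session")
def segmented(phantom_vol):
    """(bone, periosteal, labels) of the session phantom."""
    return segment(phantom_vol, SegmentationConfig())


def make_prism(nx: int, ny: int, nz: int, E: float = 10000.0,
               nu: float = 0.0, h: float = 0.082):
    """Homogeneous full prism mesh with a single-tissue modulus."""
    mask = np.ones((nx, ny, nz), dtype=bool)
    vol = DensityVolume(np.full((nx, ny, nz), 1200.0, dtype=np.float32),
                        voxel_size=h)
    mesh = build_mesh(mask, "STM", vol=vol)
    mesh.poisson = nu
    assign_stm(mesh, E)
    return mesh


def porous_mask(shape, fill=0.7, seed=0):
    """Random porous voxel mask guaranteed to span the axial direction."""
    rng = np.random.default_rng(seed)
    mask = rng.random(shape) < fill
    mask[shape[0] // 2, shape[1] // 2, :] = True  # ensure a load path
    return mask
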