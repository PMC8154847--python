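import numpy as np
import pytest

from mtfe import (
    ElasticMaterial,
    PhantomSpec,
    VoxelImage,
    make_phantom,
    voxels_to_hex_mesh,
)

H = 0.0104  # mm, in vivo protocol voxel size


@pytest.fixture
def spacing():
    return H


@pytest.fixture
def prism_mask():
    """1×1×10-voxel prism mask (the bar-theory oracle geometry)."""
    return VoxelImage(np.ones((1, 1, 10), np.uint8), H, value_kind="mask")


@pytest.fixture
def prism_mesh(prism_mask):
    return voxels_to_hex_mesh(prism_mask)


@pytest.fixture
def nu0_material():
    return ElasticMaterial(E=14800.0, nu=0.0)


@pytest.fixture
def small_tube():
    """Noiseless constant-TMD tube phantom, desk scale (~4.7k voxels)."""
    spec = PhantomSpec(
        shape="tube",
        outer_size=16 * H,
        inner_size=9 * H,
        length=32 * H,
        spacing=H,
        tmd=1100.0,
        noise_sd=0.0,
        margin=2,
    )
    return spec, make_phantom(spec)
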