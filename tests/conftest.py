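import numpy as np
import pytest

from hpft import HpftConfig, fixtures
from hpft.core import hpft_register


@pytest.fixture(scope="session")
def plane_texture():
    return fixtures.generate_textured_plane(560, 480, seed=1)


@pytest.fixture(scope="session")
def small_texture():
    return fixtures.generate_textured_plane(192, 160, seed=2)


@pytest.fixture(scope="session")
def affine_truth():
    ang = 0.03
    return np.array(
        [
            [np.cos(ang), -np.sin(ang), 6.0],
            [np.sin(ang), np.cos(ang), -4.0],
            [0.0, 0.0, 1.0],
        ]
    )


@pytest.fixture(scope="session")
def plane_scene(plane_texture, affine_truth):
    """560x480 single-plane scene with a known affine warp and noise sigma 5."""
    return fixtures.warp_scene(plane_texture, affine_truth, noise_sigma=5.0, seed=2)


@pytest.fixture(scope="session")
def plane_registration(plane_scene):
    return hpft_register(
        plane_scene.reference_image, plane_scene.target_image, None, HpftConfig(seed=7)
    )


@pytest.fixture(scope="session")
def piecewise_scene():
    """Two-plane scene whose warp bends across a fold, noise sigma 5."""
    return fixtures.generate_piecewise_planar_scene(2, seed=3, noise_sigma=5.0)


@pytest.fixture(scope="session")
def piecewise_registration(piecewise_scene):
    return hpft_register(
        piecewise_scene.reference_image, piecewise_scene.target_image, None, HpftConfig(seed=7)
    )
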