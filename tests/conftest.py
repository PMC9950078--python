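import numpy as np
import pytest

from drujkin.phantom import (
    AcquisitionProtocol,
    build_default_scene,
    fit_grid,
    rasterize,
)
from drujkin.segmentation import default_thresholds, segment_bone


def seed_voxel_for(scene, bone, vol):
    """A voxel inside the bone's cortical shell at mid-shaft, away from the gap."""
    a = np.asarray(bone.shaft_start, float)
    b = np.asarray(bone.shaft_end, float)
    mid = 0.5 * (a + b)
    other = scene.ulna if bone is scene.radius else scene.radius
    away = np.sign(a[1] - np.asarray(other.shaft_start)[1]) or -1.0
    mid[1] += away * (bone.shaft_semiaxes[0] - bone.cortical_thickness / 2.0)
    return tuple(int(i) for i in np.round(vol.index_from_world(mid)[0]).astype(int))


@pytest.fixture(scope="session")
def scene():
    return build_default_scene()


@pytest.fixture(scope="session")
def grid(scene):
    return fit_grid(scene, (1.2, 1.2, 1.2))


@pytest.fixture(scope="session")
def source_volume(scene, grid):
    """Noise-free source with the pipeline's band-limited (gauss) edge."""
    return rasterize(scene, None, grid, profile="gauss")


@pytest.fixture(scope="session")
def protocol():
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def radius_mesh(scene, source_volume):
    seed = seed_voxel_for(scene, scene.radius, source_volume)
    return segment_bone(source_volume, seed, default_thresholds(scene))


@pytest.fixture(scope="session")
def ulna_mesh(scene, source_volume):
    seed = seed_voxel_for(scene, scene.ulna, source_volume)
    return segment_bone(source_volume, seed, default_thresholds(scene))
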