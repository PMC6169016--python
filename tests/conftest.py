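import numpy as np
import pytest

from rhizospec.bandselect import ROISet
from rhizospec.hypercube import HyperCube, normalize
from rhizospec.synthscene import PRESETS, SceneParams, generate_scene


@pytest.fixture(scope="session")
def ci_scene():
    """Small seeded scene shared across the suite."""
    return generate_scene(PRESETS["ci"], seed=1)


@pytest.fixture(scope="session")
def ci_cube(ci_scene):
    """Normalized reflectance cube of the shared scene."""
    return normalize(ci_scene.raw, ci_scene.calibration)


@pytest.fixture(scope="session")
def ci_rois(ci_scene):
    """ROIs emulating hand labelling of ~0.6% of the image pixels."""
    return scene_rois(ci_scene, fraction=0.006, seed=7)


def scene_rois(scene, fraction=0.006, seed=7):
    rng = np.random.default_rng(seed)
    root = np.argwhere(scene.mask & ~scene.dead_pixels)
    soil = np.argwhere(~scene.mask & ~scene.dead_pixels)
    n = max(int(fraction * scene.mask.size / 2), 40)
    return ROISet(
        root[rng.choice(len(root), size=min(n, len(root)), replace=False)],
        soil[rng.choice(len(soil), size=min(n, len(soil)), replace=False)],
    )


@pytest.fixture
def small_cube():
    """64x64x50 smooth synthetic cube for pre-treatment exercises."""
    rng = np.random.default_rng(0)
    wl = np.linspace(1000, 1700, 50)
    base = 0.4 + 0.1 * np.sin(wl / 200.0)
    data = base[None, None, :] * (1 + 0.05 * rng.normal(size=(64, 64, 1)))
    data += 0.01 * rng.normal(size=(64, 64, 50))
    return HyperCube(data.astype(np.float32), wl)
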