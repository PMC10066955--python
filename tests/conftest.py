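"""Shared fixtures: small deterministic scenes and hand-built rasters."""

import numpy as np
import pytest

from lrcensus import SceneSpec, generate_scene, tile_orthomosaic

GRASS = np.array([125, 158, 82], dtype=np.uint8)
DARK_GREEN = np.array([45, 110, 40], dtype=np.uint8)


def draw_disk(rgb, center, radius, color=DARK_GREEN):
    yy, xx = np.mgrid[: rgb.shape[0], : rgb.shape[1]]
    inside = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2
    rgb[inside] = color
    return inside


@pytest.fixture()
def grass_tile():
    """Flat grass-coloured 256x256 RGB tile with no plants."""
    return np.tile(GRASS, (256, 256, 1))


@pytest.fixture(scope="session")
def small_scene():
    """1024x1024 scene, weed-free and unclumped, with its ground truth."""
    spec = SceneSpec(
        rng_seed=7, weed_density=0.0, clump_fraction=0.0, plant_density=1.0,
        size_range=(0.04, 0.20),
    )
    return generate_scene(spec)


@pytest.fixture(scope="session")
def small_scene_tiled(small_scene):
    ortho, truth = small_scene
    tiles, index = tile_orthomosaic(ortho, 512)
    return ortho, truth, tiles, index
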