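"""Shared synthetic fixtures.

Scenes are generated once per session at sizes small enough for fast tests
but large enough to host vessels, myelin and all four cell classes.
"""

import numpy as np
import pytest

from snarfpy.scene import SceneConfig, generate_scene
from snarfpy import separation as sep
from snarfpy import segmentation as seg

MIXING = np.array([[1.0, 0.2], [0.45, 1.0]])


def small_config(**overrides):
    base = dict(
        volume_shape_voxels=(96, 96, 96),
        n_cells=70,
        vessel_density=8,
        seed=1,
    )
    base.update(overrides)
    return SceneConfig(**base)


@pytest.fixture(scope="session")
def clean_scene():
    """Noiseless small scene: (vol_t1, vol_t2, truth)."""
    cfg = small_config(noise_gaussian_sd=0.0, noise_poisson_scale=0.0)
    return generate_scene(cfg)


@pytest.fixture(scope="session")
def noisy_scene():
    """Small scene with the default Gaussian + Poisson noise."""
    return generate_scene(small_config(seed=4))


@pytest.fixture(scope="session")
def clean_separated(clean_scene):
    """Vessel mask and unmixed maps for the clean scene."""
    v1, v2, truth = clean_scene
    vessels = sep.extract_vessels(v1, v2)
    lipid, protein, residual = sep.unmix(v1, sep.UnmixingModel(MIXING), vessels)
    return {"vessels": vessels, "lipid": lipid, "protein": protein,
            "residual": residual}


@pytest.fixture(scope="session")
def clean_segmented(clean_scene, clean_separated):
    v1, _, _ = clean_scene
    cells = seg.segment_cells(clean_separated["lipid"], clean_separated["protein"],
                              v1.voxel_size)
    caps = seg.segment_capillaries(clean_separated["vessels"], v1.voxel_size)
    return {"cells": cells, "capillaries": caps}


@pytest.fixture(scope="session")
def default_clean_scene():
    """Full default-geometry scene, noise disabled (flow/width oracles)."""
    cfg = SceneConfig(seed=2, noise_gaussian_sd=0.0, noise_poisson_scale=0.0)
    return generate_scene(cfg)
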