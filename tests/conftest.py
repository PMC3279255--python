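"""Shared fixtures: a small virtual rig and one reconstructed plant.

The expensive render+reconstruct round trip is done once per session at
reduced camera resolution and shared by the reconstruction, trait and
pipeline tests.
"""

import numpy as np
import pytest

from codedlight import synthetic as syn
from codedlight.pipeline import simulate_and_reconstruct


@pytest.fixture(scope="session")
def rig_small():
    return syn.default_rig(cam_shape=(288, 384))


@pytest.fixture(scope="session")
def mats_small(rig_small):
    return rig_small.matrices()


@pytest.fixture(scope="session")
def rig_full():
    return syn.default_rig()


@pytest.fixture(scope="session")
def mats_full(rig_full):
    return rig_full.matrices()


@pytest.fixture(scope="session")
def plant_scene():
    return syn.make_plant(seed=11)


@pytest.fixture(scope="session")
def plant_recon(plant_scene, rig_small):
    return simulate_and_reconstruct(plant_scene, rig_small, noise_sd=0.01, seed=11)


@pytest.fixture(scope="session")
def flat_leaf_render(rig_small):
    """Noiseless render of a single horizontal leaf at z = 80 mm."""
    scene = syn.make_single_leaf_scene(tilt_deg=0.0, area_cm2=30.0, center_z=80.0)
    captures, truth = syn.render_capture_set(scene, rig_small, noise_sd=0.0, seed=0)
    return scene, captures, truth
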