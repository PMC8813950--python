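"""Shared fixtures: small synthetic scenes generated at test time."""

import numpy as np
import pytest

from forestcloud import classify_scene
from forestcloud.synth import SceneConfig, fixture_scene_config, generate_scene


@pytest.fixture(scope="session")
def scene():
    """Default 64×64, 5-year fixture scene with type and hourly stacks."""
    return generate_scene(
        fixture_scene_config(include_cloud_types=True, include_hourly=True))


@pytest.fixture(scope="session")
def classmap(scene):
    return classify_scene(scene)


@pytest.fixture(scope="session")
def noisefree_scene():
    """Noise-free linear scene: every window estimate is exact."""
    return generate_scene(fixture_scene_config(
        noise_sd_spatial=0.0, noise_sd_interannual=0.0, water_fraction=0.0))


@pytest.fixture(scope="session")
def noisefree_classmap(noisefree_scene):
    return classify_scene(noisefree_scene)


@pytest.fixture(scope="session")
def null_scene():
    """No-effect scene (both sensitivities zero) with widespread small
    disturbances so that plenty of windows are triggered."""
    return generate_scene(SceneConfig(
        n_lat=128, n_lon=128, years=(2002, 2006), seed=19,
        S_tree_true=0.0, S_ele_true=0.0,
        loss_patch_count=90, loss_patch_size=6,
        water_fraction=0.0, include_monthly=False))


@pytest.fixture(scope="session")
def null_classmap(null_scene):
    return classify_scene(null_scene)


@pytest.fixture(scope="session")
def hotspot_scene():
    """Intensive-loss scene emulating a deforestation hotspot region."""
    return generate_scene(SceneConfig(
        n_lat=64, n_lon=64, years=(2002, 2018), seed=7,
        loss_patch_count=14, loss_patch_size=60,
        noise_sd_spatial=0.0, noise_sd_interannual=0.0,
        water_fraction=0.0, include_monthly=False))


@pytest.fixture(scope="session")
def hotspot_classmap(hotspot_scene):
    return classify_scene(hotspot_scene)
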