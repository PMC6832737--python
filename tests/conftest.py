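import numpy as np
import pytest

from maizestand import ScenePlan, default_camera, simulate_scene


@pytest.fixture(scope="session")
def cam_small():
    """Portrait study camera at 4 m with a reduced pixel count (fast tests)."""
    return default_camera(4.0, resolution_scale=0.4)


@pytest.fixture(scope="session")
def clean_scene(cam_small):
    """One noise-free rendered scene: regular spacings, no confounders."""
    plan = ScenePlan(spacing_sd=0.0, p_missing=0.0, p_double=0.0,
                     weed_density=0.0, residue_density=0.0, rng_seed=11)
    image, truth = simulate_scene(plan, cam_small)
    return plan, image, truth


@pytest.fixture(scope="session")
def noisy_scene(cam_small):
    """One scene under the default (study-like) stochastic conditions."""
    plan = ScenePlan(rng_seed=5)
    image, truth = simulate_scene(plan, cam_small)
    return plan, image, truth
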