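import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fcnm.grid_io import ReferenceGrid
from fcnm import synthetic_data as sd

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid3mm() -> ReferenceGrid:
    """Small fully-unmasked 3 mm grid with the SPM-style MNI affine layout."""
    shape = (16, 18, 16)
    affine = np.array(
        [
            [-3.0, 0.0, 0.0, 21.0],
            [0.0, 3.0, 0.0, -27.0],
            [0.0, 0.0, 3.0, -21.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )
    return ReferenceGrid(shape, affine, np.ones(shape, dtype=bool))


@pytest.fixture(scope="session")
def small_scene() -> sd.SyntheticScene:
    """Two-acupoint scene sized for fast end-to-end tests."""
    scene = sd.gen_scene(rng_seed=7)
    scene.n_subjects = 8
    scene.n_timepoints = 60
    return scene


@pytest.fixture(scope="session")
def small_connectome(small_scene):
    return sd.gen_connectome(small_scene)
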