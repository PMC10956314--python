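import warnings

import numpy as np
import pytest

from mesocell.model import (Box, CompartmentSpec, EnvironmentSpec,
                            InitialCondition, ModelSpec, SpeciesDef)

# the default cooperative constants include one association constant just
# above the advisory range; that warning is expected and not under test
warnings.filterwarnings(
    "ignore", message=".*outside the typical association range.*")


def minimal_model(n_steps: int = 10, **env_kw) -> ModelSpec:
    """One species, one compartment, no reactions."""
    env = EnvironmentSpec(nx=3, ny=3, nz=3, voxel_len=0.2, timestep=1e-6,
                          n_steps=n_steps, **env_kw)
    return ModelSpec(
        environment=env,
        compartments=[CompartmentSpec("box",
                                      boxes=[Box(0, 3, 0, 3, 0, 3)])],
        species=[SpeciesDef("A", "particle", 1.0,
                            allowed_compartments=["box"])],
        initial_conditions=[InitialCondition("A", "count", 5)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_model():
    return minimal_model()
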