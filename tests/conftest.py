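import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from cultepi import (
    ModelParams,
    SampleSet,
    SyntheticSpec,
    generate_landscape,
    generate_sites,
)


@pytest.fixture(scope="session")
def default_params() -> ModelParams:
    return ModelParams(gamma=3.0, zeta=1e-5, epsilon=0.0, phi=2.0)


@pytest.fixture(scope="session")
def epi_samples() -> SampleSet:
    """Medium synthetic sample set generated under the epidemiological model.

    200k cells with gamma=3.5, zeta=5e-5, eps=1e-6: roughly a hundred
    sites, enough for stable inference in unit tests.
    """
    spec = SyntheticSpec(
        n_cells=200_000,
        model_params=ModelParams(gamma=3.5, zeta=5e-5, epsilon=1e-6, phi=2.0),
        seed=1234,
    )
    grid = generate_landscape(spec)
    return generate_sites(grid, spec)


@pytest.fixture(scope="session")
def null_samples() -> SampleSet:
    """Synthetic samples whose sites are density-independent (null model)."""
    spec = SyntheticSpec(
        n_cells=200_000,
        generating_model="null",
        model_params={"k": 5e-4},
        seed=987,
    )
    grid = generate_landscape(spec)
    return generate_sites(grid, spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
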