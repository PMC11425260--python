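import numpy as np
import pytest

from caflux.model import CONTROL_PARAMS, CaState, ModelParams
from caflux.synth import GeneratorConfig


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def control_params() -> ModelParams:
    return CONTROL_PARAMS


@pytest.fixture
def default_init() -> CaState:
    return CaState(0.1, 5.0)


@pytest.fixture
def small_cohort_config() -> GeneratorConfig:
    """A fast cohort: 8 cells per condition, default study conditions otherwise."""
    return GeneratorConfig(n_cells_per_condition=8, seed=42)


def random_valid_params(rng: np.random.Generator) -> ModelParams:
    return ModelParams(
        beta=float(rng.uniform(0.5, 4.0)),
        alpha=float(rng.uniform(0.2, 3.0)),
        gamma=float(rng.uniform(0.5, 4.0)),
        n=int(rng.integers(1, 7)),
        delta=float(rng.uniform(0.3, 3.0)),
        k=float(rng.uniform(0.001, 0.2)),
        k1=float(rng.uniform(0.5, 4.0)),
    )
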