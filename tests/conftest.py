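import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", max_examples=25, derandomize=True, deadline=None)
settings.load_profile("ci")

from pumpprobe.model_core import ModelParameters, phra_best_fit


@pytest.fixture(scope="session")
def best_fit() -> ModelParameters:
    """Best-fit kinetic/transduction parameters of the PhrA reporter system."""
    return phra_best_fit()


@pytest.fixture(scope="session")
def growing_best_fit(best_fit) -> ModelParameters:
    """Best-fit parameters with growth and intracellular degradation active."""
    return best_fit.with_(mu=0.58 / 60.0, lambda_i=0.63 / 60.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
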