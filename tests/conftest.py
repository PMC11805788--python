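import numpy as np
import pytest
from hypothesis import settings

from plrspca import CompositionTable

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("ci")


def random_composition(rng: np.random.Generator, n: int, D: int) -> CompositionTable:
    """Lognormal composition: generic, strictly positive, no special structure."""
    return CompositionTable(
        np.exp(rng.normal(size=(n, D))), tuple(f"p{j + 1:02d}" for j in range(D))
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
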