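import numpy as np
import pytest

from binsel import GenotypeMatrix, MarkerMap, simulate_f2
from binsel.simulate import evenly_spaced_map


@pytest.fixture(scope="session")
def small_map() -> MarkerMap:
    """21 markers, 10 cM apart, one chromosome (moderate LD)."""
    return evenly_spaced_map(200.0, 10.0)


@pytest.fixture(scope="session")
def f2_small(small_map) -> GenotypeMatrix:
    return simulate_f2(300, small_map, seed=42)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
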