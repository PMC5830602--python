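import numpy as np
import pandas as pd
import pytest

from nestshore.datamodel import CommunityMatrix
from nestshore.synthetic import ScenarioConfig, generate


@pytest.fixture(scope="session")
def mixed_dataset():
    """A small MIXED-scenario dataset shared across integration tests."""
    return generate(ScenarioConfig(scenario="MIXED", seed=11, n_sites=12, n_species=40))


@pytest.fixture
def tiny_community():
    df = pd.DataFrame(
        [[0, 5, 1], [2, 0, 0], [1, 1, 3]],
        index=["s1", "s2", "s3"],
        columns=["spA", "spB", "spC"],
    )
    return CommunityMatrix(df, period="fall")


@pytest.fixture
def rng():
    return np.random.default_rng(7)
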