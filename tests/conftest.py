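import numpy as np
import pandas as pd
import pytest

from methpattern.io import FeatureMatrix
from methpattern.synthetic_data import SimulationConfig, nine_sample_layout, simulate_methylation


@pytest.fixture
def layout() -> pd.DataFrame:
    return nine_sample_layout()


@pytest.fixture
def small_matrix(layout) -> FeatureMatrix:
    """Deterministic 12-probe pure-noise matrix on the nine-sample layout."""
    rng = np.random.default_rng(42)
    values = pd.DataFrame(
        rng.normal(size=(12, 9)),
        index=[f"cg{i:08d}" for i in range(12)],
        columns=layout["sample_id"],
    )
    return FeatureMatrix(values, layout)


@pytest.fixture(scope="session")
def small_study():
    """A 60-probe simulated study with strong effects, shared across tests."""
    return simulate_methylation(SimulationConfig(n_probes=60, seed=3))
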