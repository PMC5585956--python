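import numpy as np
import pytest

from masem import SimCellConfig, StudySet, simulate_meta


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture()
def small_studyset() -> StudySet:
    """A fixed 5-study meta-analysis (k=5, nbar=100, equal sizes)."""
    return simulate_meta(SimCellConfig(k=5, nbar=100, design="E", seed=7, replications=1), 0)
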