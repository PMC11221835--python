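import numpy as np
import pytest

from lysoscreen import AnalysisConfig, SyntheticCellSpec, generate_field


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def clustered_field():
    """One strongly clustered synthetic field with its ground truth."""
    spec = SyntheticCellSpec(seed=42, clustered_fraction=0.8)
    return generate_field(spec)


@pytest.fixture(scope="session")
def dispersed_field():
    spec = SyntheticCellSpec(seed=43, clustered_fraction=0.2)
    return generate_field(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
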