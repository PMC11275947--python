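import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small synthetic two-view dataset shared by fast tests."""
    from genet.synthetic_data import SyntheticConfig, generate_dataset

    return generate_dataset(SyntheticConfig(n_genes=10, n_cell_lines=4, seed=7))


@pytest.fixture()
def fast_config():
    """Down-scaled training configuration for smoke-level runs."""
    from genet.config import RunConfig

    return RunConfig(
        hidden_size=16, epochs=8, pretrain_epochs=4, min_epochs=1,
        fusion_steps=2, seed=7,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
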