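import pytest

from popgencore import SimulationSpec, simulate_dataset


@pytest.fixture(scope="session")
def dataset():
    """One deterministic synthetic dataset shared by read-only tests."""
    return simulate_dataset(SimulationSpec(seed=42))


@pytest.fixture(scope="session")
def chimp_model(dataset):
    return dataset.models["main"]
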