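import pytest

from metacalc.synthetic_data import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition simulated dataset shared across tests."""
    return simulate_dataset(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def written_dataset(default_dataset, tmp_path_factory):
    """The same dataset written to disk as TSV inputs."""
    directory = tmp_path_factory.mktemp("sim") / "inputs"
    default_dataset.write(directory)
    return directory
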