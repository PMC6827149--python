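import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from dloopphylo import simulate  # noqa: E402


@pytest.fixture(scope="session")
def small_config() -> simulate.SimulationConfig:
    """A small but fully structured study configuration."""
    return simulate.SimulationConfig(
        clade_sizes={"A": 40, "B": 15, "C": 25, "D": 20},
        star_lambda=0.9,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config) -> simulate.SyntheticDataset:
    return simulate.generate_dataset(small_config)


@pytest.fixture()
def dataset_on_disk(small_dataset, tmp_path):
    return simulate.write_dataset(small_dataset, tmp_path / "data")
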