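import pytest

from enamelmap import synthgrid
from enamelmap.tables_io import SampleBlock


@pytest.fixture(scope="session")
def default_dataset():
    """One simulated diced-crown dataset under the default study design."""
    cfg = synthgrid.SimulationConfig(seed=0)
    grid, records, truth = synthgrid.simulate_dataset(cfg)
    return cfg, grid, records, truth


@pytest.fixture
def tiny_grid():
    """Three blocks on one tooth plus reference-volume geometry."""
    return [
        SampleBlock("L1", "M3", 0, 0, 2.14, "secretory"),
        SampleBlock("L2", "M3", 0, 1, 1.07, "early_maturation"),
        SampleBlock("L3", "M3", 1, 0, 4.28, "DEJ"),
    ]
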