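import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from heteroscope import heterosis
from heteroscope.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """500-gene synthetic diallel dataset with 30+20 planted genes."""
    return simulate_dataset(SimulationConfig.tiny(seed=7))


@pytest.fixture(scope="session")
def tiny_heterosis(tiny_dataset):
    return heterosis.compute_heterosis(tiny_dataset.design, tiny_dataset.traits)


@pytest.fixture(scope="session")
def tiny_profiles(tiny_dataset):
    return tiny_dataset.expression.parent_profiles()
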