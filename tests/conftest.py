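import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracle.py importable

from fpattach import (
    DEFAULT_WINDOW,
    SimulationConfig,
    classify_records,
    simulate,
)
from fpattach.synthetic import fixture_physicians


@pytest.fixture(scope="session")
def window():
    return DEFAULT_WINDOW


@pytest.fixture(scope="session")
def fixture_phys():
    return fixture_physicians()


@pytest.fixture(scope="session")
def sim_default():
    """One shared default-mixture simulation, 20,000 patients."""
    config = SimulationConfig(seed=20080401, n_patients=20_000)
    return config, simulate(config)


@pytest.fixture(scope="session")
def classified_default(sim_default):
    config, data = sim_default
    cohort, tables, results = classify_records(
        data.patients, data.physicians, data.visits, data.spells, config.window
    )
    return config, data, cohort, tables, results
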