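import numpy as np
import pytest

from chromapop.stimuli import class_table, generate_stimulus_table
from chromapop.synth import simulate_recorded_population


@pytest.fixture(scope="session")
def table():
    return generate_stimulus_table(seed=0)


@pytest.fixture(scope="session")
def equi(table):
    return class_table(table, "equi")


@pytest.fixture(scope="session")
def angles21():
    return np.arange(21) * 360.0 / 21.0


@pytest.fixture(scope="session")
def glob_pop(table):
    return simulate_recorded_population("glob", 40, table, seed=1, n_trials=5)
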