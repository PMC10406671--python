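import pytest

from aednet import ScenarioGrid, run_grid, run_sensitivity_table


@pytest.fixture(scope="session")
def default_grid():
    return ScenarioGrid()


@pytest.fixture(scope="session")
def results_table(default_grid):
    return run_grid(default_grid)


@pytest.fixture(scope="session")
def sensitivity_table(default_grid):
    return run_sensitivity_table(default_grid)
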