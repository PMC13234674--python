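import numpy as np
import pytest

from batchtea.economics import (EconomicAssumptions, ScenarioInputs,
                                compute_opex, scenario_flows)
from batchtea.scenarios import generate_dataset


@pytest.fixture(scope="session")
def assumptions():
    return EconomicAssumptions()


@pytest.fixture(scope="session")
def baseline_inputs():
    return ScenarioInputs.baseline()


@pytest.fixture(scope="session")
def baseline_opex(baseline_inputs, assumptions):
    flows = scenario_flows(baseline_inputs)
    return compute_opex(baseline_inputs, flows, assumptions), flows


@pytest.fixture(scope="session")
def small_dataset():
    """A modest Monte Carlo table shared by the model-level tests."""
    return generate_dataset(n=400, seed=7)
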