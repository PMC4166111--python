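import numpy as np
import pytest

from ordsem.design import ConditionSpec, analysis_spec, generating_population
from ordsem.harness import study_aux_specs


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def aux_specs():
    """The study's fixed auxiliary measurement models (seed 1)."""
    return study_aux_specs(1)


@pytest.fixture(scope="session")
def simple_l0_population(aux_specs):
    cond = ConditionSpec("ignore", "both", 0, "simple", "predictor")
    return cond, generating_population(cond, aux_specs)


@pytest.fixture(scope="session")
def simple_l0_spec(simple_l0_population):
    cond, pop = simple_l0_population
    return analysis_spec(cond, pop)
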