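import numpy as np
import pytest

from latentchoice.cohort import CohortSpec, simulate_cohort, study_fixture_classes
from latentchoice.design import DesignConfig, build_default_attributes
from latentchoice.lcmnl import ChoiceData


@pytest.fixture(scope="session")
def attributes():
    return build_default_attributes()[0]


@pytest.fixture(scope="session")
def prohibitions():
    return build_default_attributes()[1]


@pytest.fixture(scope="session")
def fixture_classes():
    return study_fixture_classes()


@pytest.fixture(scope="session")
def small_cohort(fixture_classes):
    """300-respondent fixture cohort used across unit tests."""
    spec = CohortSpec(classes=fixture_classes, n_respondents=300, seed=7)
    observations, truth, design = simulate_cohort(spec)
    chosen = observations["chosen"].to_numpy(dtype=np.int64).reshape(-1, 3).argmax(axis=1)
    data = ChoiceData.from_design(design, chosen)
    return {
        "spec": spec,
        "observations": observations,
        "truth": truth,
        "design": design,
        "data": data,
        "chosen": chosen,
    }


@pytest.fixture(scope="session")
def default_design_config():
    return DesignConfig(seed=123)
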