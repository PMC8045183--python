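import numpy as np
import pytest

from scoreval import DecisionPolicy
from scoreval.synthetic import CohortDesign, ReproDesign, generate_validation_cohort


@pytest.fixture(scope="session")
def policy():
    return DecisionPolicy()


@pytest.fixture(scope="session")
def default_cohort():
    return generate_validation_cohort(CohortDesign(seed=11))


@pytest.fixture(scope="session")
def repro_design():
    return ReproDesign(seed=42)
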