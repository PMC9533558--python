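import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from dietmetals.prep import prepare_cohort
from dietmetals.simulate import CohortConfig, TrueModel, generate_cohort

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_model():
    return TrueModel.default()


@pytest.fixture(scope="session")
def small_cohort(default_model):
    """n=1,500 cohort under the default harmful-metals/protective-diet model."""
    return generate_cohort(CohortConfig(n_participants=1500, seed=11), default_model)


@pytest.fixture(scope="session")
def prepped_small(small_cohort):
    cohort, _ = prepare_cohort(small_cohort)
    return cohort


@pytest.fixture(scope="session")
def medium_cohort(default_model):
    """n=2,500 cohort for estimator behaviour checks."""
    return generate_cohort(CohortConfig(n_participants=2500, seed=23), default_model)


@pytest.fixture(scope="session")
def prepped_medium(medium_cohort):
    cohort, _ = prepare_cohort(medium_cohort)
    return cohort


@pytest.fixture()
def tiny_diet():
    """Three participants with two synthetic components for hand-checks."""
    return pd.DataFrame(
        {
            "comp_a": [60.0, 30.0, 90.0],
            "comp_b": [10.0, 20.0, 30.0],
            "total_energy": [2000.0, 1500.0, 3000.0],
        },
        index=["p1", "p2", "p3"],
    )
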