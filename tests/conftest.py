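import numpy as np
import pandas as pd
import pytest

from caplmiss import CohortParams, apply_missingness, generate_cohort


@pytest.fixture(scope="session")
def cohort_2k() -> pd.DataFrame:
    """A complete 2000-child cohort shared across read-only tests."""
    return generate_cohort(CohortParams(n=2000), seed=42)


@pytest.fixture(scope="session")
def masked_2k(cohort_2k):
    """The same cohort with the default missingness mechanism applied."""
    masked, truth = apply_missingness(cohort_2k, seed=43)
    return masked, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
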