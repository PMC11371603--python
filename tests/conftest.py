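import numpy as np
import pytest

from olzdose import default_model, fit
from olzdose.cohort import CohortSpec, make_dataset


@pytest.fixture(scope="session")
def table3_model():
    """The published final parameter estimates."""
    return default_model()


@pytest.fixture(scope="session")
def cohort39(table3_model):
    """A seeded 39-subject synthetic replica of the TDM cohort."""
    return make_dataset(CohortSpec(), table3_model, seed=7)


@pytest.fixture(scope="session")
def fit39(cohort39, table3_model):
    """Final-model fit on the 39-subject replica (shared: fits are costly)."""
    result = fit(cohort39, table3_model, seed=0)
    assert result.converged
    return result


@pytest.fixture(scope="session")
def tiny_fixture(table3_model):
    """A 3-subject dataset for brute-force likelihood cross-checks."""
    return make_dataset(CohortSpec(n_subjects=3), table3_model, seed=123)


def rel_err(a, b):
    return abs(a - b) / abs(b)
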