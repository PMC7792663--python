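import numpy as np
import pytest

from selfreg.synthetic import default_spec, generate_cohort
from selfreg.wait_model import fit_at_params, fit_tobit_re


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def cohort():
    """One default-size synthetic cohort shared across tests."""
    return generate_cohort(default_spec(seed=11))


@pytest.fixture(scope="session")
def fitted(cohort):
    """Maximum-likelihood wait-model fit on the shared cohort."""
    return fit_tobit_re(cohort.wait_records)


@pytest.fixture(scope="session")
def oracle_fit(cohort):
    """Wait-model object evaluated at the generating truth (no refit)."""
    return fit_at_params(cohort.wait_records, cohort.spec.tobit_params)
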