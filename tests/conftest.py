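import numpy as np
import pytest

from edusem import load_table1_fixture, to_covariance
from edusem.summary_data import MomentInput, VariableSet


@pytest.fixture(scope="session")
def sm():
    """The printed 12-variable summary table."""
    return load_table1_fixture()


@pytest.fixture(scope="session")
def moments(sm):
    """Covariance-form fitter input at the cohort n."""
    return to_covariance(sm)


def make_moments(names, roles, cov, n_eff=500, mean=None):
    """Small helper for toy fitter inputs."""
    vs = VariableSet(names=tuple(names), roles=roles)
    return MomentInput(variables=vs, cov=np.asarray(cov, dtype=float), mean=mean, n_eff=n_eff)


@pytest.fixture(scope="session")
def toy3():
    """PD 3-variable moments for just-identified factor / saturation checks."""
    cov = np.array([[1.0, 0.5, 0.3], [0.5, 1.0, 0.4], [0.3, 0.4, 1.0]])
    return make_moments(
        ("a", "b", "c"), {"a": "early_iq", "b": "education", "c": "subtest"}, cov, n_eff=500
    )
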