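import numpy as np
import pytest

from lactopk import fixtures
from lactopk.generate import generate_study


@pytest.fixture(scope="session")
def pop_ref():
    """Published population model (IIV column read as log-variance)."""
    return fixtures.table3_population()


@pytest.fixture(scope="session")
def theta_ref(pop_ref):
    return pop_ref.theta


@pytest.fixture(scope="session")
def table2():
    return fixtures.table2_averages()


@pytest.fixture(scope="session")
def table2_ds():
    return fixtures.table2_dataset()


@pytest.fixture(scope="session")
def small_lactating_ds(pop_ref):
    """One noisy single-dose lactating study (8 subjects)."""
    return generate_study("singledose_lactating", pop_ref, seed=3, residual=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
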