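import numpy as np
import pytest

from amykit.kinetic_models import MacroscopicRates
from amykit.synthetic_data import gen_dose_series, gen_tht_plate


@pytest.fixture(scope="session")
def default_rates():
    return MacroscopicRates(lam=0.02, kappa=1.0, theta=0.323)


@pytest.fixture(scope="session")
def primary_series():
    """One seeded primary-perturbation dose series with its ground truth."""
    return gen_dose_series(seed=11, process="nu_n")


@pytest.fixture(scope="session")
def control_plate():
    """A seeded single-condition raw ThT plate with blanks."""
    return gen_tht_plate(seed=7)


@pytest.fixture
def hour_grid():
    return np.linspace(0.0, 24.0, 289)
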