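import numpy as np
import pytest

from mssfit import (
    build_autoreg,
    build_immigration_death,
    build_lotka_volterra,
    gillespie_simulate,
)

ID_THETA = np.array([0.6, 0.03])
LV_THETA = np.array([0.5, 0.0025, 0.3])
AR_THETA = np.array([0.1, 0.7, 0.35, 0.3, 0.1, 0.9, 0.2, 0.1])


@pytest.fixture(scope="session")
def id_net():
    return build_immigration_death()


@pytest.fixture(scope="session")
def lv_net():
    return build_lotka_volterra()


@pytest.fixture(scope="session")
def ar_net():
    return build_autoreg(10)


@pytest.fixture(scope="session")
def id_series(id_net):
    """21-point immigration-death series at dt=2 from the steady state."""
    return gillespie_simulate(id_net, [20], 2.0 * np.arange(21), ID_THETA, seed=7)


@pytest.fixture(scope="session")
def lv_series(lv_net):
    """40-point Lotka-Volterra series at dt=1 from (71, 79)."""
    return gillespie_simulate(lv_net, [71, 79], 1.0 * np.arange(40), LV_THETA, seed=3)
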