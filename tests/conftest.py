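import numpy as np
import pytest

from statelump.fixtures import (
    glucose_carrier_lump,
    glucose_transport,
    photosynthesis_6state,
    photosynthesis_26state,
)


@pytest.fixture(scope="session")
def m6():
    return photosynthesis_6state()


@pytest.fixture(scope="session")
def m26():
    return photosynthesis_26state()


@pytest.fixture(scope="session")
def glucose():
    return glucose_transport()


@pytest.fixture(scope="session")
def carrier_lump():
    return glucose_carrier_lump()


@pytest.fixture(scope="session")
def traj26(m26):
    from statelump.simulate import default_time_grid, simulate

    return simulate(m26, default_time_grid(m26))


def birth_death_fractions(rates_up, rates_down):
    """Independent oracle: stationary distribution of a reversible chain.

    ``rates_up[i]`` drives state i -> i+1, ``rates_down[i]`` the reverse.
    Detailed balance gives pi_{i+1} = pi_i * up_i / down_i.
    """
    pi = [1.0]
    for up, down in zip(rates_up, rates_down):
        pi.append(pi[-1] * up / down)
    pi = np.array(pi)
    return pi / pi.sum()
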