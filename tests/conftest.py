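import numpy as np
import pytest

from atriafib import cell_models as cmod
from atriafib.monodomain import default_profiles, prepaced_initial_states


@pytest.fixture(scope="session")
def la_profile():
    return cmod.RemodelingProfile.for_region("left_atrium")


@pytest.fixture(scope="session")
def ra_profile():
    return cmod.RemodelingProfile.for_region("right_atrium")


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def prepaced(profiles):
    """Region-wise myocyte states after the 2 equilibration beats."""
    return prepaced_initial_states(profiles)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20211015)


def random_myocyte_states(rng, n):
    """Clamped myocyte states spanning the physiological range."""
    states = []
    for _ in range(n):
        y = np.empty(21)
        y[0] = rng.uniform(-95.0, 40.0)
        y[1:16] = rng.uniform(0.0, 1.0, 15)
        y[16] = rng.uniform(5.0, 20.0)       # Na_i
        y[17] = rng.uniform(120.0, 150.0)    # K_i
        y[18] = rng.uniform(5e-5, 1e-3)      # Ca_i
        y[19] = rng.uniform(0.5, 3.0)        # Ca_up
        y[20] = rng.uniform(0.5, 3.0)        # Ca_rel
        states.append(y)
    return states
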