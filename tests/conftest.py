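import numpy as np
import pytest

import sleepdyn as sd


@pytest.fixture(scope="session")
def small_session():
    """A quick neocortex-like session: 30 neurons, 120 s per state."""
    spec = sd.SessionSpec(
        n_neurons=30,
        schedule=sd.default_schedule(120.0, 120.0, 120.0),
        seed=123,
    )
    return sd.gen_session(spec)


@pytest.fixture(scope="session")
def standard_session():
    """Full-size session at the study's conditions (50 neurons, 300 s/state)."""
    return sd.gen_session(sd.SessionSpec(seed=7))


@pytest.fixture(scope="session")
def cohort():
    """Eight independent sessions at the study's conditions, 360 s per state."""
    base = sd.SessionSpec(schedule=sd.default_schedule(360.0, 360.0, 360.0))
    return sd.gen_cohort(8, base, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
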