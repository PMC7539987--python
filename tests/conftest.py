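import numpy as np
import pytest

from xcquench import correlate, kinetics
from xcquench.types import LightSchedule, PigmentProfile, Segment


@pytest.fixture(scope="session")
def cv_vitro():
    return kinetics.default_model("chlorella")


@pytest.fixture(scope="session")
def at_vitro():
    return kinetics.default_model("arabidopsis")


@pytest.fixture(scope="session")
def cv_vivo():
    return kinetics.default_model("chlorella", "in_vivo")


@pytest.fixture(scope="session")
def initial_pool():
    return PigmentProfile(vio=3.0, ant=0.0, zea=0.0)


@pytest.fixture(scope="session")
def hl_schedule():
    """Continuous high-light NPQ protocol: 1 min dark, 25 min at
    2000 µmol m⁻² s⁻¹, 10 min dark recovery."""
    return correlate.npq_schedule(2000.0)


@pytest.fixture(scope="session")
def hl_simulation(cv_vivo, hl_schedule, initial_pool):
    return kinetics.simulate_in_vivo(cv_vivo, hl_schedule, initial_pool)


@pytest.fixture(scope="session")
def dtt_simulation(cv_vivo, initial_pool):
    sched = correlate.npq_schedule(2000.0, inhibitor=True)
    return kinetics.simulate_in_vivo(cv_vivo, sched, initial_pool)


@pytest.fixture(scope="session")
def two_cycle_schedule():
    return LightSchedule(segments=(
        Segment(60, 0.0), Segment(300, 2000.0), Segment(300, 0.0),
        Segment(300, 2000.0), Segment(300, 0.0)))


@pytest.fixture(scope="session")
def irradiance_sweep(cv_vivo):
    return correlate.sweep_irradiance(cv_vivo)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
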