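import pytest
from hypothesis import HealthCheck, settings

from hebbtone import (
    AmplitudeSignature,
    SweepSchedule,
    ToneLattice,
    TrainingParams,
    train,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_lattice():
    """3 octaves at 100-cent resolution: 36 tones, trains in milliseconds."""
    return ToneLattice(resolution_cents=100.0, n_octaves=3)


@pytest.fixture(scope="session")
def linear5():
    return AmplitudeSignature.linear(5)


@pytest.fixture(scope="session")
def tencent_run(linear5):
    """The desk-scale study condition: 10-cent lattice, 3 sweeps, 2 repetitions.

    Trained once per session; several analyses read from it.
    """
    lattice = ToneLattice(resolution_cents=10.0)
    schedule = SweepSchedule(order="ascending", n_sweeps=3, repetitions=2)
    state = train(lattice, linear5, schedule, TrainingParams())
    return lattice, state
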