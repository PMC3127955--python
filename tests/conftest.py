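import pytest
from hypothesis import HealthCheck, settings

from anisosmooth import DesignSchedule, KernelSpec, ObserverSpec, simulate_experiment

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_design() -> DesignSchedule:
    return DesignSchedule()


@pytest.fixture(scope="session")
def estimated_kernel() -> KernelSpec:
    """Group-mean kernel estimate: vertically elongated aperture."""
    return KernelSpec(a_h=0.84, a_v=2.08, r=0.0)


@pytest.fixture(scope="session")
def one_participant_design() -> DesignSchedule:
    return DesignSchedule(participants=1)


@pytest.fixture(scope="session")
def simulated_table(one_participant_design):
    """One synthetic participant under the default observer."""
    return simulate_experiment(one_participant_design, [ObserverSpec(seed=12345)])
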