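import numpy as np
import pytest

from sleepnirs import OpticalConfig, PhysioParams, RunConfig
from sleepnirs.simulate import DesatDistribution


@pytest.fixture(scope="session")
def optics() -> OpticalConfig:
    return OpticalConfig()


@pytest.fixture()
def quiet_physio() -> PhysioParams:
    """Noiseless physiology with one fixed 4% event, zero venous lag."""
    return PhysioParams(
        venous_lag_s=0.0,
        events_per_condition={"baseline": 1},
        desat_magnitude_dist=DesatDistribution(kind="fixed", median_pct=4.0),
    ).without_noise()


@pytest.fixture(scope="session")
def small_run() -> RunConfig:
    """A short default-noise pipeline configuration used by several tests."""
    return RunConfig(
        duration_s=1800.0,
        conditions=("baseline", "cpap:8"),
        physio=PhysioParams(events_per_condition={"baseline": 3, "cpap:8": 3}),
        seed=42,
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
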