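import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from parattc import ObserverConfig, TrajectorySpec, generate_dataset, paper_trajectory_set


@pytest.fixture(scope="session")
def spec_gs50():
    """Mid-set trajectory: zero GS error designed at 50% of a 3-s flight."""
    return TrajectorySpec(
        z_init=25.16, x_end=10.06, z_end=-5.03, flight_time=3.0,
        gs_rel=0.5, traj_id="gs50",
    )


@pytest.fixture(scope="session")
def spec_gs30():
    return TrajectorySpec(
        z_init=23.49, x_end=15.09, z_end=-4.53, flight_time=3.0,
        gs_rel=0.3, traj_id="gs30",
    )


@pytest.fixture(scope="session")
def head_on_spec():
    """Ball lands on the observer: the GS model is exact throughout."""
    return TrajectorySpec(z_init=25.16, x_end=0.0, z_end=1e-9, flight_time=3.0)


@pytest.fixture(scope="session")
def paper_set():
    return paper_trajectory_set()


@pytest.fixture(scope="session")
def paper_set_sides():
    return paper_trajectory_set(include_sides=True)


@pytest.fixture(scope="session")
def small_config():
    """A reduced cohort for fast pipeline tests: 4 participants x 1 block."""
    return ObserverConfig(n_participants=4, n_early=2, n_blocks=1)


@pytest.fixture(scope="session")
def small_trials(small_config):
    return generate_dataset(small_config, seed=11)
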