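import numpy as np
import pytest

from dyadreach.model import MotionPlan, PlantParams, WristState


@pytest.fixture(scope="session")
def plant() -> PlantParams:
    return PlantParams()


@pytest.fixture()
def rest_pair() -> tuple[WristState, WristState]:
    x = WristState(-10.0, 0.0, 0.0, 0.0)
    return (x, x)


@pytest.fixture(scope="session")
def position_priority_plan() -> MotionPlan:
    return MotionPlan(q_pos=25.0, q_vel=0.01)


@pytest.fixture(scope="session")
def velocity_priority_plan() -> MotionPlan:
    return MotionPlan(q_pos=2.5, q_vel=0.05)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
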