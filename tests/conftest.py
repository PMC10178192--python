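import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from careassign import HelperType, Instance

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_random_instance(
    rng: np.random.Generator, m: int, n: int, robot_prob: float = 0.5
) -> Instance:
    """A random instance respecting the type-structural zeros: caregivers
    carry no utilization, robots no stress."""
    types = tuple(
        HelperType.ROBOT if rng.random() < robot_prob else HelperType.CAREGIVER
        for _ in range(n)
    )
    robot = np.array([t is HelperType.ROBOT for t in types], dtype=bool)
    c = rng.random((m, n))
    a = rng.random((m, n))
    b = rng.random((m, n))
    a[:, ~robot] = 0.0
    b[:, robot] = 0.0
    return Instance(
        elderly_ids=tuple(f"E{i + 1:02d}" for i in range(m)),
        helper_ids=tuple(f"H{j + 1:02d}" for j in range(n)),
        helper_types=types,
        efficiency=c,
        utilization=a,
        stress=b,
    )


@pytest.fixture
def random_instance_factory():
    return make_random_instance


@pytest.fixture
def one_elderly_two_helpers() -> Instance:
    """One elderly person, a caregiver (c=0.9, b=0.2) and a robot
    (c=0.4, a=0.8)."""
    return Instance(
        elderly_ids=("e1",),
        helper_ids=("cg", "rb"),
        helper_types=(HelperType.CAREGIVER, HelperType.ROBOT),
        efficiency=[[0.9, 0.4]],
        utilization=[[0.0, 0.8]],
        stress=[[0.2, 0.0]],
    )


@pytest.fixture
def two_by_three_instance() -> Instance:
    """Fixed 2-elderly x 3-helper instance (caregiver, robot, caregiver)."""
    return Instance(
        elderly_ids=("e1", "e2"),
        helper_ids=("h1", "h2", "h3"),
        helper_types=(HelperType.CAREGIVER, HelperType.ROBOT, HelperType.CAREGIVER),
        efficiency=[[0.8, 0.3, 0.6], [0.5, 0.7, 0.4]],
        utilization=[[0.0, 0.9, 0.0], [0.0, 0.2, 0.0]],
        stress=[[0.1, 0.0, 0.5], [0.6, 0.0, 0.3]],
    )
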