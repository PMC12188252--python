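import numpy as np
import pytest

from morphoridge.energetics import MaterialParams
from morphoridge.pattern import GrowthSchedule
from morphoridge.solver import solve_hierarchy


@pytest.fixture(scope="session")
def params4() -> MaterialParams:
    """Quartic-interaction study parameters."""
    return MaterialParams(m=4, mu=10.0)


@pytest.fixture(scope="session")
def linear_schedule() -> GrowthSchedule:
    """Sustained linear growth: L = 1 + t, delta = t."""
    return GrowthSchedule.linear(L0=1.0, g=1.0)


@pytest.fixture(scope="session")
def study_trajectory(params4, linear_schedule):
    """The package's default m=4 hierarchy run (reused across tests)."""
    return solve_hierarchy(
        params4, linear_schedule, t_max=20.0, max_level=8, dt=0.01
    )


@pytest.fixture(scope="session")
def two_level_trajectory(params4, linear_schedule):
    return solve_hierarchy(
        params4, linear_schedule, t_max=8.0, max_level=2, dt=0.01
    )
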