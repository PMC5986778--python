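import math

import pytest

from treesway.config import SYNTHETIC_CONFIG
from treesway.core import OscillatorParameters
from treesway.fitting import analyze
from treesway.simulate import SimulationSpec, generate_trajectory

# a realistic pole-like-tree parameter set: two close natural frequencies
# around 21.6/21.86 rad/s, light unequal damping, axis at 52.5 degrees
TABLE_PARAMS = OscillatorParameters(
    omega1=21.56,
    omega2=21.86,
    delta1=0.52,
    delta2=0.64,
    alpha=math.radians(52.5),
    X0=10.0,
    Y0=5.0,
)


@pytest.fixture(scope="session")
def table_trajectory():
    """Noiseless 30 s / 100 Hz pull-and-release record at TABLE_PARAMS."""
    return generate_trajectory(
        SimulationSpec(TABLE_PARAMS, duration=30.0, sample_rate=100.0)
    )


@pytest.fixture(scope="session")
def table_result(table_trajectory):
    """Full analysis of the reference synthetic record (computed once)."""
    return analyze(table_trajectory, SYNTHETIC_CONFIG)
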