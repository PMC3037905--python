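import itertools

import numpy as np
import pytest

from nucleocurve.curvature import CurvatureParams, RollTiltTable

STEPS = ["".join(p) for p in itertools.product("ACGT", repeat=2)]


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def zero_table():
    return RollTiltTable({s: (0.0, 0.0) for s in STEPS})


@pytest.fixture
def roll_one_table():
    """All steps roll 1 degree, tilt 0: a homogeneous bending table."""
    return RollTiltTable({s: (1.0, 0.0) for s in STEPS})


@pytest.fixture
def random_table(rng):
    return RollTiltTable(
        {s: (float(r), float(t))
         for s, (r, t) in zip(STEPS, rng.normal(0, 5, size=(16, 2)))}
    )


@pytest.fixture
def default_params():
    return CurvatureParams()


def brute_force_curvature(steps, table, nu0=10.4):
    """Independent oracle: direct complex summation, term by term."""
    total = 0j
    for j, s in enumerate(steps):
        rho, tau = table[s]
        total += complex(rho, -tau) * complex(
            np.cos(2 * np.pi * j / nu0), np.sin(2 * np.pi * j / nu0)
        )
    return abs(nu0 / len(steps) * total)
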