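import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from axotrace import TransportSimConfig, simulate_transport
from axotrace.tracking import RunRuleConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def rules():
    return RunRuleConfig()


@pytest.fixture
def small_config():
    """Quick-to-simulate movie used by several modules."""
    return TransportSimConfig(n_particles=6, n_frames=80, seed=7)


@pytest.fixture
def small_movie(small_config):
    return simulate_transport(small_config)


def random_walk_track(rng, n_frames, tol):
    """Random battery track mixing stalls, sub-tolerance jitter and runs."""
    steps = []
    while len(steps) < n_frames - 1:
        kind = rng.integers(0, 4)
        length = int(rng.integers(1, 7))
        if kind == 0:            # dead stall
            steps += [0.0] * length
        elif kind == 1:          # sub-tolerance jitter
            steps += list(rng.uniform(-0.9 * tol, 0.9 * tol, length))
        else:                    # directed motion, either way
            sign = 1 if kind == 2 else -1
            steps += list(sign * rng.uniform(1.5 * tol, 1.2, length))
    steps = steps[: n_frames - 1]
    return np.concatenate([[0.0], np.cumsum(steps)]) + 30.0
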