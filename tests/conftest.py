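import numpy as np
import pytest

from l1census.ephys_features import VoltageTrace
from l1census.morphology import Morphology


@pytest.fixture
def flat_trace():
    """A quiet sweep at rest, 10 kHz, 500 ms."""
    t = np.arange(0.0, 500.0, 0.1)
    return VoltageTrace(t, np.full_like(t, -65.0), np.zeros_like(t),
                        {"cell_id": "flat", "sweep_id": 0,
                         "sampling_rate_khz": 10.0})


@pytest.fixture
def y_tree():
    """Soma + axon trunk bifurcating into two straight daughters at 90 deg."""
    ids = np.array([1, 2, 3, 4, 5, 6, 7])
    parents = np.array([-1, 1, 2, 3, 3, 1, 6])
    structs = np.array([1, 2, 2, 2, 2, 3, 3])
    xyz = np.array([
        [0.0, 0.0, 0.0],
        [0.0, 10.0, 0.0],
        [0.0, 20.0, 0.0],    # branch point
        [10.0, 30.0, 0.0],   # daughter 1 (45 deg left of vertical)
        [-10.0, 30.0, 0.0],  # daughter 2 (45 deg right) -> 90 deg between
        [5.0, -5.0, 0.0],
        [15.0, -15.0, 0.0],
    ])
    radius = np.full(7, 1.0)
    return Morphology(ids, parents, structs, xyz, radius)
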