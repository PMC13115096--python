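import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from dihypernet import DirectedHypergraph, EdgeKind, GrowthConfig, grow_directed_social


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def star_network():
    """One-way hyperedge: 4 tail nodes all following a single hub."""
    H = DirectedHypergraph(5)
    H.add_edge(EdgeKind.ONE_WAY, {1, 2, 3, 4}, {0})
    return H


@pytest.fixture(scope="session")
def small_social():
    """A 400-node social hypernetwork, shared across read-only tests."""
    return grow_directed_social(GrowthConfig(N=400, seed=77))
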