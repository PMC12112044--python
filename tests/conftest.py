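import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from payloadgnn.synthetic import generate_random_graphs


@pytest.fixture(scope="session")
def small_graphs():
    """A pool of connected random graphs (≤10 nodes, 5 features)."""
    return generate_random_graphs(30, node_range=(1, 10), feature_dim=5, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
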