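import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def uniform_reference():
    """A 1000-tag uniform reference profile."""
    from restamp import ReferenceProfile

    k = 1000
    ids = tuple(f"t{i}" for i in range(k))
    return ReferenceProfile(ids, np.full(k, 1.0 / k))
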