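import sys
from pathlib import Path

import numpy as np
import pytest

from flymotion import ModelParams

sys.path.insert(0, str(Path(__file__).parent))  # makes _naive importable


@pytest.fixture
def params():
    return ModelParams()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_frames(rng):
    """Small random uint8 sequence for oracle-equivalence checks."""
    return rng.integers(0, 256, size=(10, 20, 20), dtype=np.uint8)
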