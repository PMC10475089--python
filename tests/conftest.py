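import numpy as np
import pytest

from sptpalm import build_cell


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def typical_cell():
    """A typical rod-shaped cell: 5 µm long, 1 µm wide."""
    return build_cell(5.0, 1.0)
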