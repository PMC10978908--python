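import numpy as np
import pytest

from umbpipe.synthdata import random_transcripts


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_reference(rng):
    """Ten random 400-bp transcripts."""
    return random_transcripts(10, 400, rng)
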