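import numpy as np
import pytest

from pepgibbs import Config, validate_config


@pytest.fixture
def flat_config():
    """Default validated config: L=9, indels off, flat background."""
    return validate_config(Config())


@pytest.fixture
def indel_config():
    """Case-study geometry: L=9, up to 1 insertion and 2 deletions."""
    return validate_config(Config(max_insertion_length=1,
                                  max_deletion_length=2))


@pytest.fixture
def rng():
    return np.random.default_rng(123)
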