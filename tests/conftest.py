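import numpy as np
import pytest

from plumm.model import ModelParams, build_templates
from plumm.rhythm import fixtures


@pytest.fixture(scope="session")
def templates():
    """Default metered/unmetered template pair at full contrast."""
    return build_templates()


@pytest.fixture(scope="session")
def default_params():
    """Simulation defaults: p_switch 0.01, contrast 1.0, prior 0.5."""
    return ModelParams()


@pytest.fixture(scope="session")
def nine_fixtures():
    """The nine reference rhythms, low -> medium -> high complexity."""
    return fixtures()


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)
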