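import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the reference oracles

from taskguide.config import default_module


@pytest.fixture(scope="session")
def module():
    """The shipped six-step egg-boiling task module."""
    return default_module()
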