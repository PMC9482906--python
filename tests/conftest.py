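import numpy as np
import pytest

from steroquant.panel import default_panel
from steroquant.simulate import GeneratorConfig


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture
def make_config(panel):
    """GeneratorConfig factory sharing the session panel (fast)."""

    def _make(seed=0, **kwargs):
        return GeneratorConfig(seed=seed, panel=panel, **kwargs)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
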