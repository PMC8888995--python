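import numpy as np
import pytest

from spermscreen.synthetic import DEFAULT_CLASS_PARAMS, MotilityClassParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def pm_clean():
    """A progressive class with no speed spread or localization noise."""
    return MotilityClassParams("PM", 50.0, 0.0, 1.0, 0.0)


@pytest.fixture
def class_params():
    return dict(DEFAULT_CLASS_PARAMS)
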