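import numpy as np
import pytest


@pytest.fixture
def labels_10_13():
    """Binary labels for the reference two-group design: 10 MS, 13 HC."""
    return np.array([1.0] * 10 + [0.0] * 13)


@pytest.fixture
def separated_predictor(labels_10_13):
    """A generically spaced predictor that perfectly separates the groups."""
    rng = np.random.default_rng(7)
    return np.concatenate([rng.normal(0.0, 1.0, 10), rng.normal(10.0, 1.0, 13)])
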