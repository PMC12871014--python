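import numpy as np
import pytest

from asrt.datagen import TrialDesignConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def null_config():
    """Global-null two-arm design: equal survival and response everywhere."""
    return TrialDesignConfig(surv3=(0.5, 0.5, 0.5), resp_rate=(0.5, 0.5, 0.5),
                             tau=0.5)


def exp_sample(rng, n, hazard, horizon):
    """Exponential survival administratively censored at a fixed horizon."""
    t = rng.exponential(1.0 / hazard, size=n)
    ev = (t <= horizon).astype(int)
    return np.minimum(t, horizon), ev
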