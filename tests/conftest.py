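import numpy as np
import pytest

from t2oa.signal_models import BEParams, EchoSchedule, MEParams, NoiseModel, SEParams


@pytest.fixture(scope="session")
def seven_pte():
    """The 7-image protocol schedule with repeated 33/55 ms preparations."""
    return EchoSchedule.default_seven()


@pytest.fixture(scope="session")
def healthy_be():
    """Whole-cartilage bi-exponential medians of the healthy group."""
    return BEParams(amplitude=1.0, f=0.22, t2_short=5.7, t2_long=54.1)


@pytest.fixture(scope="session")
def healthy_se():
    return SEParams(amplitude=1.0, t2=24.7, alpha=0.31)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
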