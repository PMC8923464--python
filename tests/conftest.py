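import numpy as np
import pytest

from anpitch import frontend as fe


@pytest.fixture(scope="session")
def front():
    return fe.HeinzFrontend()


@pytest.fixture(scope="session")
def thr_map(front):
    return fe.calibrate_rate_level_thresholds(front)
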