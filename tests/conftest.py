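import numpy as np
import pytest

from nirsglm.probe_signal import default_probe


@pytest.fixture(scope="session")
def geometry():
    return default_probe()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
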