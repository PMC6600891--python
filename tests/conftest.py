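import numpy as np
import pytest

import rofseg as rs


@pytest.fixture(scope="session")
def easy_sample():
    """One default-condition synthetic sample, shared across tests."""
    return rs.synth_sample(rs.SynthConfig(seed=0))


@pytest.fixture(scope="session")
def easy_result(easy_sample):
    """Whole-preset segmentation of the shared sample's channel A."""
    return rs.segment_sample(easy_sample.img_A, easy_sample.img_dapi,
                             rs.PRESETS["whole"])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
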