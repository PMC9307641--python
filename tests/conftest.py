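import numpy as np
import pytest

from pathomil.labeler import GazetteerIndex, load_gazetteer


@pytest.fixture(scope="session")
def gazetteer():
    return GazetteerIndex(load_gazetteer())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
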