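import numpy as np
import pytest

from brainecf import load_bundle


@pytest.fixture(scope="session")
def bundle():
    return load_bundle()


@pytest.fixture(scope="session")
def grid240():
    return np.linspace(0.0, 240.0, 241)
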