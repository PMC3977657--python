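import numpy as np
import pytest

from cdqc import build_default_references, make_session


@pytest.fixture(scope="session")
def refs():
    return build_default_references(seed=0)


@pytest.fixture(scope="session")
def clean_session():
    return make_session(seed=1)


@pytest.fixture(scope="session")
def clean_bundle(clean_session):
    return clean_session.to_bundle()


@pytest.fixture
def grid():
    return np.arange(175.0, 280.0 + 0.5, 1.0)
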