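import pytest

from dopafba import make_skeleton_model, skeleton_groups
from dopafba.synthetic import micro_fixtures


@pytest.fixture(scope="session")
def skeleton():
    return make_skeleton_model()


@pytest.fixture(scope="session")
def groups():
    return skeleton_groups()


@pytest.fixture(scope="session")
def fixtures():
    return micro_fixtures()
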