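import pytest

from dimerfold import STUDY_SEQUENCES, load_parameters


@pytest.fixture(scope="session")
def params():
    return load_parameters()


@pytest.fixture(scope="session")
def study():
    return STUDY_SEQUENCES
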