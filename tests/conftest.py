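import pytest

from radact import load_seed_lexicon
from radact.structurer import default_config


@pytest.fixture(scope="session")
def lexicon():
    return load_seed_lexicon()


@pytest.fixture(scope="session")
def config():
    return default_config()
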