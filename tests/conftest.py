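import pytest

from sdohkit.lexicon import load_lexicon
from sdohkit.llm import MockBackend
from sdohkit.rbs import default_cue_rules_path, default_lexicon_path, load_cue_rules
from sdohkit.schema import load_taxonomy


@pytest.fixture(scope="session")
def tax():
    return load_taxonomy()


@pytest.fixture(scope="session")
def lex(tax):
    return load_lexicon(default_lexicon_path(), tax)


@pytest.fixture(scope="session")
def cue_rules():
    return load_cue_rules(default_cue_rules_path())


@pytest.fixture(scope="session")
def mock_backend(lex, tax):
    return MockBackend.from_lexicon(lex, tax)
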