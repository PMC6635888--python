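import numpy as np
import pytest

from speechmaps.language import CorpusConfig, build_corpus, build_lexicon


@pytest.fixture(scope="session")
def default_corpus():
    """The full 210-item model-language corpus at default settings."""
    return build_corpus(CorpusConfig(seed=0))


@pytest.fixture(scope="session")
def default_lexicon(default_corpus):
    return default_corpus.lexicon


@pytest.fixture(scope="session")
def tiny_corpus():
    """Small corpus (6 words, 18 items) for fast training tests."""
    from speechmaps.fixtures import make_fixture

    return make_fixture("tiny-corpus", seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
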