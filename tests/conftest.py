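import pytest

from formamentis.fixtures import (
    FixtureSpec,
    fallback_parse,
    make_mini_lexicons,
    make_topic_corpus,
)


@pytest.fixture(scope="session")
def spec():
    return FixtureSpec(seed=7)


@pytest.fixture(scope="session")
def mini(spec):
    return make_mini_lexicons(spec)


@pytest.fixture(scope="session")
def bundle(mini):
    return mini.bundle


@pytest.fixture(scope="session")
def topic_corpus(spec):
    return make_topic_corpus(spec)


@pytest.fixture(scope="session")
def parser():
    return fallback_parse


@pytest.fixture(scope="session")
def tfmn(topic_corpus, bundle, parser):
    """One network pooling every topic's documents."""
    from formamentis.network import assemble_tfmn

    docs = [d for ds in topic_corpus.documents_by_topic.values() for d in ds]
    return assemble_tfmn(docs, bundle, parser)
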