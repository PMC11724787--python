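import pytest

from copmine import (
    GoldTreeBackend,
    SyntheticSpec,
    generate_corpus,
    run_extraction,
)

CORPUS_SEED = 7


@pytest.fixture(scope="session")
def corpus():
    """The default seeded synthetic corpus: (spec, articles, gold, parses)."""
    spec = SyntheticSpec(random_seed=CORPUS_SEED)
    articles, gold, parses = generate_corpus(spec)
    return spec, articles, gold, parses


@pytest.fixture(scope="session")
def gold_backend(corpus):
    _, _, _, parses = corpus
    return GoldTreeBackend(parses)


@pytest.fixture(scope="session")
def pipeline_result(corpus, gold_backend):
    """Filter -> match -> extract over the default corpus."""
    _, articles, _, _ = corpus
    return run_extraction(articles, gold_backend)
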