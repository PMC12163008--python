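import pytest

from synthletters.fixtures import FixtureSpec, generate_letter


@pytest.fixture(scope="session")
def spec():
    return FixtureSpec(seed=101, misspelling_rate=0.02)


@pytest.fixture(scope="session")
def corpus(spec):
    """20 fixture letters with their gold labels."""
    return [generate_letter(spec, i) for i in range(20)]


@pytest.fixture(scope="session")
def letters(corpus):
    return [lt for lt, _ in corpus]


@pytest.fixture(scope="session")
def corpus_dir(tmp_path_factory, spec):
    from synthletters.fixtures import generate_corpus

    out = tmp_path_factory.mktemp("fixture_corpus")
    paths = generate_corpus(FixtureSpec(seed=202, n_letters=8, misspelling_rate=0.02), out)
    return paths
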