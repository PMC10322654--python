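import pytest

from envirule.cluster import cluster
from envirule.io import read_functional_groups
from envirule.rules import generate_ruleset
from envirule.synthetic import make_corpus


@pytest.fixture(scope="session")
def fgs():
    return read_functional_groups()


@pytest.fixture(scope="session")
def corpus():
    """Noise-free four-family corpus (oracle conditions)."""
    return make_corpus(seed=1)


@pytest.fixture(scope="session")
def noisy_corpus():
    return make_corpus(seed=1, n_noise_per_family=3)


@pytest.fixture(scope="session")
def corpus_groups(corpus, fgs):
    return cluster(corpus.reactions, fgs)


@pytest.fixture(scope="session")
def corpus_ruleset(corpus, corpus_groups, fgs):
    return generate_ruleset(
        corpus_groups, 5.0, corpus.compounds, corpus.observed(), fgs
    )
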