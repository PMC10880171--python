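import numpy as np
import pytest

from medlink import (
    ConceptEntry,
    SyntheticConfig,
    TermDictionary,
    fit_tfidf,
    generate_benchmark,
)


@pytest.fixture
def tiny_dictionary():
    """Two-term corpus used in the hand-derived TF-IDF examples."""
    return TermDictionary(
        [ConceptEntry("c1", "abc"), ConceptEntry("c2", "abd")]
    )


@pytest.fixture
def disorder_dictionary():
    """A small disorder-style dictionary with synonym structure."""
    rows = [
        ("C0021400", "influenza"),
        ("C0021400", "flu"),
        ("C0860211", "intrahepatic biliary obstruction"),
        ("C0860211", "obstruction of the intrahepatic duct"),
        ("C0011849", "diabetes mellitus"),
        ("C0011849", "diabetes"),
        ("C0020538", "hypertension"),
        ("C0020538", "high blood pressure"),
        ("C0004096", "asthma"),
        ("C0015967", "fever"),
    ]
    return TermDictionary([ConceptEntry(c, t) for c, t in rows])


@pytest.fixture(scope="session")
def small_benchmark():
    """Seconds-scale mixed-signal benchmark shared across tests."""
    return generate_benchmark(
        SyntheticConfig(n_concepts=60, n_queries=60, seed=7)
    )


@pytest.fixture(scope="session")
def small_stack(small_benchmark):
    """(dictionary, encoder, embedder) for the small benchmark."""
    encoder = fit_tfidf(small_benchmark.dictionary, {2, 3}, "paper")
    return small_benchmark.dictionary, encoder, small_benchmark.embedder()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
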