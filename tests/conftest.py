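import pytest

from ackminer.nlp_adapters import FixtureBackend, Gazetteers
from ackminer.synthetic_corpus import SynthConfig, generate_corpus


@pytest.fixture(scope="session")
def example_gazetteers() -> Gazetteers:
    """Entities appearing in the worked examples used across tests."""
    return Gazetteers(
        persons=frozenset(
            {
                "Y. Nishiyama",
                "K. Mackie",
                "Doris Thelian",
                "Peter Merrifield",
                "Stefano Schiaffino",
                "Keith Gull",
            }
        ),
        organizations=frozenset(
            {"Indiana University", "University of Oxford", "NIH"}
        ),
    )


@pytest.fixture(scope="session")
def backend(example_gazetteers) -> FixtureBackend:
    return FixtureBackend(gazetteers=example_gazetteers)


@pytest.fixture(scope="session")
def plain_backend() -> FixtureBackend:
    """Backend with the default word list and empty gazetteers."""
    return FixtureBackend()


@pytest.fixture(scope="session")
def clean_corpus():
    """Template-only corpus with no distractors: extraction should be exact."""
    return generate_corpus(
        SynthConfig(n_documents=200, distractor_rate=0.0, rng_seed=7)
    )


@pytest.fixture(scope="session")
def noisy_corpus():
    """Default-rate corpus including distractor sentences."""
    return generate_corpus(SynthConfig(n_documents=150, rng_seed=11))
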