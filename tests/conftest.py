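import pytest
from hypothesis import settings

from ddekit.synthetic import SyntheticConfig, generate, matched_mock_scorer

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_corpus():
    """200-comment synthetic corpus shared by pipeline tests."""
    return generate(SyntheticConfig(n_comments=200, seed=11))


@pytest.fixture(scope="session")
def clean_scorer(small_corpus):
    """Mock scorer matched to the small corpus, noiseless."""
    return matched_mock_scorer(small_corpus.manifest, noise=0.0)
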