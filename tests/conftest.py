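import pytest

from clintern.embedding_features import MockEmbeddingProvider
from clintern.synthetic_corpus import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """20 synthetic documents with bookkeeping (fixed seed)."""
    return generate_corpus(GeneratorConfig(n_documents=20, seed=7))


@pytest.fixture(scope="session")
def tiny_provider():
    """Low-dimensional mock encoder for shape-agnostic feature tests."""
    return MockEmbeddingProvider(seed=11, hidden_size=16, n_layers=6)
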