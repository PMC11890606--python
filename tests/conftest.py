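import numpy as np
import pytest

from tweetformer import (
    ModelConfig,
    SyntheticSpec,
    TextClassifier,
    build_vocab,
    encode,
    generate_corpus,
)
from tweetformer.preprocess import normalize_document


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_corpus():
    """A small normalized corpus with a known vocabulary."""
    spec = SyntheticSpec(n_docs=60, vocab_size=40, seed=5)
    return [normalize_document(d) for d in generate_corpus(spec)]


@pytest.fixture(scope="session")
def tiny_vocab(tiny_corpus):
    return build_vocab(tiny_corpus)


def debug_config(**overrides) -> ModelConfig:
    """A miniature configuration for gradient checks and fast smoke tests."""
    base = dict(
        max_len=6,
        embed_dim=4,
        lstm_hidden=3,
        n_heads=2,
        d_h=2,
        dropout=0.0,
        epochs=1,
        batch_size=4,
        dtype="float64",
    )
    base.update(overrides)
    return ModelConfig(**base)


@pytest.fixture
def debug_model(tiny_vocab):
    cfg = debug_config()
    return TextClassifier(cfg, tiny_vocab)


def encode_corpus(docs, vocab, max_len):
    return [encode(d, vocab, max_len) for d in docs]
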