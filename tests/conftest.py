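import numpy as np
import pytest

import sentdec as sd


@pytest.fixture(scope="session")
def small_corpus() -> sd.Corpus:
    spec = sd.CorpusSpec(n_examples=120, vocab_size=80, lexicon_size_per_class=8,
                         marker_pool_size=4, sentence_length_range=(7, 12),
                         seed=11)
    return sd.generate_corpus(spec)


@pytest.fixture(scope="session")
def tiny_model(small_corpus) -> sd.GatedSentimentClassifier:
    """A quickly trained model shared by inference/explanation tests."""
    tr, va, _ = sd.split_corpus(small_corpus, (0.7, 0.15, 0.15), seed=0)
    clf = sd.GatedSentimentClassifier(
        embed_dim=16, n_layers=1, n_heads=2, ffn_hidden=32, pool_hidden=8,
        epochs=2, batch_size=16, learning_rate=0.01, preset="full", seed=0)
    clf.fit_corpus(tr, validation=va)
    return clf


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
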