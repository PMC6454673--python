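import numpy as np
import pytest

from rannote import (
    DictSegmenter,
    GeneratorConfig,
    document_to_sequences,
    generate_corpus,
)


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    return GeneratorConfig(n_documents=10, sentences_per_doc=5, seed=7)


@pytest.fixture(scope="session")
def small_corpus(small_config):
    return generate_corpus(small_config)


@pytest.fixture(scope="session")
def small_segmenter(small_config):
    return DictSegmenter(small_config.dictionary())


@pytest.fixture(scope="session")
def small_sequences(small_corpus, small_segmenter):
    return [
        s for doc in small_corpus for s in document_to_sequences(doc, small_segmenter)
    ]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
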