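import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hanscribe import synthgen, textprep, training
from hanscribe.transcripts import CleanTranscript

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


TINY_CONFIG = dict(gru_units=3, attn_dim=2, embed_dim=4, dtype="float64")


@pytest.fixture
def tiny_config():
    """Minimal dimensions for exact/numeric tests (double precision)."""
    return training.TrainConfig(**TINY_CONFIG)


@pytest.fixture(scope="session")
def small_corpus():
    """A small balanced synthetic corpus shared by cheap tests."""
    return synthgen.generate_corpus(
        synthgen.SynthConfig(n_docs_per_class=20, seed=7)).transcripts


@pytest.fixture(scope="session")
def small_vocab(small_corpus):
    return textprep.build_vocab(small_corpus)


@pytest.fixture
def two_sentence_doc():
    return CleanTranscript(
        doc_id="doc-0",
        sentences=[["the", "boy", "falls", "."], ["water", "overflows", "."]],
        label="AD",
    )


def random_params(config, vocab, seed=0):
    return training.init_params(config, vocab, seed=seed)


@pytest.fixture
def tiny_params(tiny_config, small_vocab):
    return random_params(tiny_config, small_vocab, seed=3)


def encode_one(doc, vocab, l_max=None, t_max=None):
    l_max = l_max or doc.n_sentences
    t_max = t_max or max(len(s) for s in doc.sentences)
    return textprep.encode_batch([doc], vocab, l_max, t_max)
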