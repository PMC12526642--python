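import numpy as np
import pytest

from silentspeech.signal_model import NOISE_LABEL
from silentspeech.snn import EncoderConfig, build_reference_set, pretrain
from silentspeech.synthetic import SynthConfig, make_word_bank, synth_corpora

TINY_VOCAB = ("Need", "Land", "Here", "Us", NOISE_LABEL)
TINY_SENTENCES = (("Need", "Land"), ("Us", "Here"))


@pytest.fixture(scope="session")
def tiny_synth_config():
    return SynthConfig(n_word_reps=8, n_sentence_reps=4, seed=7)


@pytest.fixture(scope="session")
def tiny_bank(tiny_synth_config):
    return make_word_bank(TINY_VOCAB, tiny_synth_config)


@pytest.fixture(scope="session")
def tiny_corpora(tiny_synth_config):
    return synth_corpora(TINY_VOCAB, TINY_SENTENCES, tiny_synth_config)


@pytest.fixture(scope="session")
def tiny_encoder_config():
    return EncoderConfig(n_conv_blocks=2, channels=(4, 8), embedding_dim=16,
                         epochs=3, seed=7)


@pytest.fixture(scope="session")
def tiny_refs(tiny_corpora, tiny_encoder_config):
    corpus_a, _ = tiny_corpora
    return build_reference_set(corpus_a, shots_per_class=5,
                               input_length=tiny_encoder_config.input_length)


@pytest.fixture(scope="session")
def tiny_model(tiny_corpora, tiny_refs, tiny_encoder_config):
    """A small pretrained EMG model shared by inference-level tests."""
    corpus_a, _ = tiny_corpora
    return pretrain(corpus_a, tiny_refs, tiny_encoder_config, modality="emg")


@pytest.fixture
def rng():
    return np.random.default_rng(42)
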