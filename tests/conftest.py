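import numpy as np
import pytest

from memomol.fixtures import smiles_corpus
from memomol.tokenizer import build_vocabulary


@pytest.fixture(scope="session")
def corpus():
    """The default procedural corpus (5,000 valid molecules)."""
    return smiles_corpus(5000, seed=0)


@pytest.fixture(scope="session")
def small_corpus(corpus):
    return corpus[:800]


@pytest.fixture(scope="session")
def vocab(corpus):
    return build_vocabulary(corpus)


@pytest.fixture(scope="session")
def bias_base_generator(corpus):
    """A small pretrained LSTM generator shared by the biasing tests."""
    from memomol.cells import MemoryConfig
    from memomol.generator import TrainConfig, train_generator
    mem = MemoryConfig(n_locations=30, word_size=12, controller_units=24,
                       embedding_length=24)
    cfg = TrainConfig(iterations=1500, batch_size=32, eval_every=1500,
                      eval_sample=100, learning_rate=3e-3, seed=5)
    gen, log = train_generator(corpus[:3000], "lstm", cfg, mem)
    assert log[-1]["valid_pct"] > 80.0
    return gen


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
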