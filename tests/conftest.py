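import numpy as np
import pytest

from pvlm.fixtures import ToyCorpusSpec, generate_toy_corpus
from pvlm.model import Checkpoint, DualStreamModel, ModelConfig
from pvlm.properties import PropertyRegistry, fit_normalization
from pvlm.tokenizer import train_bpe


@pytest.fixture(scope="session")
def toy_corpus() -> list[str]:
    return generate_toy_corpus(ToyCorpusSpec(n=300, seed=11))


@pytest.fixture(scope="session")
def vocab(toy_corpus):
    return train_bpe(toy_corpus, vocab_size=300)


@pytest.fixture(scope="session")
def registry() -> PropertyRegistry:
    return PropertyRegistry.toy()


@pytest.fixture(scope="session")
def stats(toy_corpus, registry):
    return fit_normalization(toy_corpus, registry)


@pytest.fixture(scope="session")
def tiny_config(vocab) -> ModelConfig:
    return ModelConfig(hidden_dim=32, n_layers_unimodal=1, n_layers_fusion=1,
                       n_heads=4, n_properties=12, vocab_size=len(vocab),
                       contrastive_dim=16, max_smiles_len=64)


@pytest.fixture(scope="session")
def tiny_ckpt(tiny_config, vocab, registry, stats) -> Checkpoint:
    """Randomly initialized (untrained) checkpoint for mechanical tests."""
    model = DualStreamModel(tiny_config, seed=123)
    return Checkpoint(model=model, vocab=vocab, registry=registry, stats=stats)
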