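import numpy as np
import pytest

from dualscreen.corpus import stratified_split
from dualscreen.model import MultitaskTextModel
from dualscreen.synthetic import GeneratorConfig, generate_corpus
from dualscreen.training import TrainConfig


@pytest.fixture(scope="session")
def strong_corpus():
    """Strong-signal synthetic corpus used by the model-level tests."""
    return generate_corpus(GeneratorConfig.strong_signal(n_records=600, seed=1))


@pytest.fixture(scope="session")
def strong_split(strong_corpus):
    return stratified_split(strong_corpus, seed=1)


@pytest.fixture(scope="session")
def fitted(strong_split):
    """One fitted multitask model shared across evaluation tests."""
    model = MultitaskTextModel(strong_split)
    return model.fit(TrainConfig.desk_scale(seed=0))


@pytest.fixture(scope="session")
def vae_fixture():
    """A trained conditional VAE on a small imbalanced corpus."""
    from dualscreen.vae import VAEConfig, train_vae

    corpus = generate_corpus(
        GeneratorConfig(n_records=300, seed=5, imbalance={"mild": 0.55, "moderate": 0.3, "severe": 0.15})
    )
    config = VAEConfig(latent_dim=16, enc_hidden=32, dec_hidden=48, epochs=15, seed=5)
    vae, tok = train_vae(corpus, config)
    return corpus, config, vae, tok


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
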