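import numpy as np
import pytest

import molssl as M


@pytest.fixture(scope="session")
def small_corpus():
    """120-molecule, 4-family synthetic corpus shared across unit tests."""
    spec = M.SynthSpec(n_molecules=120, n_families=4, seed=11)
    corpus, families = M.generate_corpus(spec)
    return corpus, families


@pytest.fixture(scope="session")
def small_fingerprints(small_corpus):
    corpus, _ = small_corpus
    return np.asarray([M.compute_maccs(m) for m in corpus], dtype=float)


@pytest.fixture(scope="session")
def tiny_encoder_config():
    return M.EncoderConfig(n_layers=3, hidden_dim=16, graph_dim=24,
                           latent_dim=8, seed=0)


@pytest.fixture(scope="session")
def tiny_encoder(tiny_encoder_config):
    return M.init_encoder(tiny_encoder_config)
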