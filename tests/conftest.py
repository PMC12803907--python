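import numpy as np
import pytest

from planttf.seqio import LabeledCorpus, ProteinRecord
from planttf.synth import SyntheticConfig, generate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """Three easy motif families plus background; cheap enough for unit tests."""
    config = SyntheticConfig(
        n_families=3,
        family_sizes=(40, 30, 20),
        motif_length=8,
        mutation_rate=0.02,
        length_range=(60, 120),
        n_background=20,
        seed=7,
    )
    corpus, manifest = generate_corpus(config)
    return corpus, manifest


@pytest.fixture
def toy_records():
    return [
        ProteinRecord("a", "MKVLA"),
        ProteinRecord("b", "GGHMK"),
        ProteinRecord("c", "MKVLA"),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
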