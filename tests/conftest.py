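import numpy as np
import pytest

from foldear.deep_model import TrainConfig
from foldear.fusion_classify import FusionPipeline
from foldear.synthetic_barn import CorpusSpec, generate_corpus, load_corpus

REFERENCE_SEED = 7
REFERENCE_N_PER_CLASS = 60
REFERENCE_SAMPLE_RATE = 16_000


@pytest.fixture(scope="session")
def reference_corpus_dir(tmp_path_factory):
    """The reference synthetic corpus: 60 segments/class, 16 kHz, seed 7."""
    out = tmp_path_factory.mktemp("corpus")
    generate_corpus(
        CorpusSpec(
            n_per_class=REFERENCE_N_PER_CLASS,
            sample_rate=REFERENCE_SAMPLE_RATE,
            seed=REFERENCE_SEED,
        ),
        out,
    )
    return out


@pytest.fixture(scope="session")
def reference_segments(reference_corpus_dir):
    return load_corpus(reference_corpus_dir)


@pytest.fixture(scope="session")
def pipeline(reference_segments):
    """Shared fusion pipeline; CNNs are trained lazily, once per session."""
    return FusionPipeline(
        reference_segments, seed=REFERENCE_SEED, train_config=TrainConfig(seed=REFERENCE_SEED)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
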