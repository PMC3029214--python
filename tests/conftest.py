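import dataclasses

import numpy as np
import pytest

from voicelevel.config import SystemConfig
from voicelevel.evaluation import extract_features
from voicelevel.synthetic_voice import default_profile, generate_corpus


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def mini_corpus():
    """Small 16 kHz corpus: 2 children per level, 2 repetitions (80 utterances)."""
    profile = dataclasses.replace(default_profile(16000), duration_s=(0.45, 0.55))
    records, truth = generate_corpus(
        profile, n_children_per_level={1: 2, 2: 2, 3: 2, 4: 2}, reps_per_word=2, seed=5
    )
    return records, truth


@pytest.fixture(scope="session")
def mini_features(mini_corpus):
    records, _ = mini_corpus
    return extract_features(records)


@pytest.fixture(scope="session")
def small_config():
    """Classifier sizes matched to the mini corpus (full sizes need more data)."""
    return SystemConfig(hmm_n_states=4, hmm_n_mix=2, em_max_iter=15, mlp_epochs=500)
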