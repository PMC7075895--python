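import warnings

import numpy as np
import pytest

from speechstate.lexicon import default_lexicon
from speechstate.semantic import build_semantic_model
from speechstate.synth import (CohortConfig, SubjectProfile, generate_cohort,
                               generate_corpus)

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def corpus(lexicon):
    return generate_corpus(lexicon)


@pytest.fixture(scope="session")
def semantic_model(corpus):
    return build_semantic_model(corpus)


@pytest.fixture(scope="session")
def flat_profile():
    """A deterministic subject profile with mid-range parameters."""
    return SubjectProfile(base_f0=120.0, base_jitter=1.5, base_shimmer=3.0,
                          base_pause_rate=8.0, base_speech_rate=4.0,
                          base_concept_weight=0.10,
                          topic_preference=np.full(12, 1 / 12),
                          verbosity=300.0)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory, lexicon):
    """Four subjects, two conditions, both tasks, desk-scale recordings."""
    cfg = CohortConfig(n_subjects=4, conditions=("PBO", "MDMA1.5"),
                       tasks=("Monologue", "Description"),
                       duration_s=70.0, sample_rate=16000, seed=11)
    out = tmp_path_factory.mktemp("cohort")
    return generate_cohort(cfg, out, lexicon=lexicon, write_corpus=False)
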