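import numpy as np
import pytest
from hypothesis import settings

import emovid
from emovid.partitioning import assign_splits, loso_difficulty_scores, split_records
from emovid.segmentation import segment_record

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_corpus():
    """Default-condition synthetic corpus, gap-free, segmented to the
    emotional phase.  Session-scoped: several suites share it."""
    corpus = emovid.generate_corpus(emovid.SyntheticConfig(seed=0))
    return [segment_record(r) for r in corpus]


@pytest.fixture(scope="session")
def default_splits(default_corpus):
    scores = loso_difficulty_scores(default_corpus)
    assignment = assign_splits(scores)
    return split_records(default_corpus, assignment)


@pytest.fixture(scope="session")
def tiny_corpus():
    """A small, fast corpus: 6 subjects, 2-4 videos per emotion."""
    counts = {l: (4 if l.valence == "negative" else 2) for l in emovid.EmotionLabel}
    cfg = emovid.SyntheticConfig(n_subjects=6, per_emotion_counts=counts, seed=7)
    return emovid.generate_corpus(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
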