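import numpy as np
import pytest

from l2speech.design import StudyDesign
from l2speech.speech_io import build_token_table
from l2speech.study import generate_study

TINY_DESIGN = StudyDesign(
    n_participants=4, n_active=2, tokens_per_phoneme=1, repetitions=1
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def tiny_study(tmp_path_factory):
    """A small but complete on-disk study: 4 participants, 2 sessions,
    1 word per phoneme, 1 repetition -> 48 vowel + 64 consonant tokens."""
    root = tmp_path_factory.mktemp("tiny_study")
    dataset = generate_study(TINY_DESIGN, out_dir=root, seed=11)
    return dataset


@pytest.fixture(scope="session")
def tiny_tokens(tiny_study):
    tokens, issues = build_token_table(tiny_study.root)
    assert not issues
    return tokens
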