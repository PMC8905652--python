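import numpy as np
import pytest

from syllastream import lexicon as lx
from syllastream import stream as sm


@pytest.fixture(scope="session")
def syllabary_a() -> lx.Lexicon:
    return lx.load_canonical_syllabary("A")


@pytest.fixture(scope="session")
def syllabary_b() -> lx.Lexicon:
    return lx.load_canonical_syllabary("B")


@pytest.fixture(scope="session")
def default_sequence(syllabary_a) -> sm.WordSequence:
    """A full default stream (480 word tokens), fixed seed."""
    return sm.generate_word_sequence(syllabary_a, seed=20240101)


@pytest.fixture(scope="session")
def short_sequence(syllabary_a) -> sm.WordSequence:
    """A reduced stream (2 reps/block, 96 word tokens) for EEG-sized tests."""
    return sm.generate_word_sequence(syllabary_a, reps_per_block=2, seed=7)


@pytest.fixture(scope="session")
def short_timeline(short_sequence) -> sm.Timeline:
    return sm.build_timeline(short_sequence)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
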