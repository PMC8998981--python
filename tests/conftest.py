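import numpy as np
import pytest

from pwmsa.io import ALPHABET, ProteinSequence, SequenceSet
from pwmsa.pwm import ScoringParams


@pytest.fixture
def params():
    return ScoringParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_sequence(rng, length, seq_id="s"):
    return ProteinSequence(
        seq_id, "".join(rng.choice(list(ALPHABET), size=length))
    )


def random_set(rng, n, length):
    return SequenceSet(
        [random_sequence(rng, length, f"s{i}") for i in range(n)]
    )


@pytest.fixture
def small_set(rng):
    return random_set(rng, 5, 30)
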