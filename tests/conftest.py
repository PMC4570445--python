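import numpy as np
import pytest

from ecgrbp.core import RankProfile, WordSequence, count_and_rank


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_profile(rng, m=4, n_words=200):
    words = rng.integers(0, 1 << m, size=n_words)
    return count_and_rank(WordSequence(words=words, m=m))


def profile_from_words(words, m):
    return count_and_rank(WordSequence(words=np.asarray(words), m=m))


def profile_from_freqs_ranks(freqs, ranks, m):
    """Build a RankProfile directly from stated freqs/ranks (hand examples)."""
    return RankProfile(m=m, freqs=np.asarray(freqs, dtype=float),
                       ranks=np.asarray(ranks, dtype=np.int64))
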