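"""Reduced binary pattern (RBP) primitives.

An ECG trace is reduced to a binary sequence by comparing strided sample
pairs, the binary sequence is chopped into overlapping ``m``-bit words, and
the word histogram is converted into a rank profile — the feature object
every downstream comparison operates on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "ECGSignal",
    "RBPParams",
    "BinarySequence",
    "WordSequence",
    "RankProfile",
    "reduce_binary",
    "words_from_bits",
    "count_and_rank",
    "profile_signal",
    "ranks_from_counts",
]


@dataclass(frozen=True)
class ECGSignal:
    """A raw single-lead ECG sample sequence.

    Parameters
    ----------
    samples : array-like of float
        Amplitudes in arbitrary units (ADC counts or mV); never rescaled.
    fs : float
        Sampling rate in Hz.
    subject_id, record_id : str, optional
        Opaque labels carried through the pipeline.
    timestamp : str, optional
        ISO date(/time) of acquisition; used to order long-term records.
    """

    samples: np.ndarray
    fs: float
    subject_id: Optional[str] = None
    record_id: Optional[str] = None
    timestamp: Optional[str] = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if samples.size < 2:
            raise ValueError("signal too short: need at least 2 samples")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass(frozen=True)
class RBPParams:
    """Algorithm knobs.

    m      -- word length in bits (2**m counters are allocated)
    alpha  -- stride of the sample-pair comparison (1 = consecutive samples)
    beta   -- minimum rise in amplitude for a comparison to emit a 1
    gamma  -- blend weight of the incremental model update (evolving only)
    """

    m: int = 8
    alpha: int = 1
    beta: float = 0.0
    gamma: float = 0.5

    def __post_init__(self) -> None:
        if not (isinstance(self.m, (int, np.integer)) and 1 <= self.m <= 16):
            raise ValueError("m must be an integer in [1, 16]")
        if not (isinstance(self.alpha, (int, np.integer)) and self.alpha >= 1):
            raise ValueError("alpha must be an integer >= 1")
        if not self.beta >= 0:
            raise ValueError("beta must be >= 0")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")


@dataclass(frozen=True)
class BinarySequence:
    """Bit sequence produced by :func:`reduce_binary`."""

    bits: np.ndarray
    source_length: int
    alpha_used: int = 1

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=np.uint8)
        if bits.size and not np.isin(bits, (0, 1)).all():
            raise ValueError("bits must contain only 0 and 1")
        object.__setattr__(self, "bits", bits)

    def __len__(self) -> int:
        return self.bits.size


@dataclass(frozen=True)
class WordSequence:
    """Overlapping m-bit words as integers in ``[0, 2**m - 1]``."""

    words: np.ndarray
    m: int

    def __post_init__(self) -> None:
        words = np.asarray(self.words, dtype=np.int64)
        if words.size and (words.min() < 0 or words.max() > (1 << self.m) - 1):
            raise ValueError("word values out of range for m")
        object.__setattr__(self, "words", words)

    def __len__(self) -> int:
        return self.words.size


@dataclass(frozen=True)
class RankProfile:
    """Count / frequency / rank statistics of one segment or model.

    ``ranks`` is a full permutation of ``1..2**m`` (1 = most frequent);
    ties in counts are broken toward the smaller word value so the profile
    is deterministic.  ``counts`` is ``None`` for profiles synthesised from
    blended frequencies (evolving models), where only ``freqs`` is
    authoritative.
    """

    m: int
    freqs: np.ndarray
    ranks: np.ndarray
    counts: Optional[np.ndarray] = None
    total_words: int = 0

    def __post_init__(self) -> None:
        size = 1 << self.m
        freqs = np.asarray(self.freqs, dtype=float)
        ranks = np.asarray(self.ranks, dtype=np.int64)
        if freqs.shape != (size,) or ranks.shape != (size,):
            raise ValueError(f"freqs/ranks must have length 2**m = {size}")
        if np.any(freqs < 0):
            raise ValueError("freqs must be non-negative")
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError("freqs must sum to 1")
        if sorted(ranks.tolist()) != list(range(1, size + 1)):
            raise ValueError("ranks must be a permutation of 1..2**m")
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "ranks", ranks)
        if self.counts is not None:
            counts = np.asarray(self.counts, dtype=np.int64)
            if counts.shape != (size,):
                raise ValueError("counts must have length 2**m")
            if counts.sum() != self.total_words:
                raise ValueError("sum(counts) must equal total_words")
            object.__setattr__(self, "counts", counts)

    @classmethod
    def from_counts(cls, counts: np.ndarray, m: int) -> "RankProfile":
        counts = np.asarray(counts, dtype=np.int64)
        total = int(counts.sum())
        if total <= 0:
            raise ValueError("empty profile: no words counted")
        freqs = counts / total
        return cls(m=m, freqs=freqs, ranks=ranks_from_counts(counts),
                   counts=counts, total_words=total)

    @classmethod
    def from_freqs(cls, freqs: np.ndarray, m: int) -> "RankProfile":
        """Profile backed only by a frequency vector (renormalised)."""
        freqs = np.asarray(freqs, dtype=float)
        s = freqs.sum()
        if s <= 0:
            raise ValueError("empty profile: frequencies sum to 0")
        freqs = freqs / s
        return cls(m=m, freqs=freqs, ranks=ranks_from_counts(freqs))

    def to_dict(self) -> dict:
        return {
            "m": self.m,
            "total_words": self.total_words,
            "counts": None if self.counts is None else self.counts.tolist(),
            "freqs": self.freqs.tolist(),
            "ranks": self.ranks.tolist(),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "RankProfile":
        counts = d.get("counts")
        return cls(
            m=int(d["m"]),
            freqs=np.asarray(d["freqs"], dtype=float),
            ranks=np.asarray(d["ranks"], dtype=np.int64),
            counts=None if counts is None else np.asarray(counts, dtype=np.int64),
            total_words=int(d.get("total_words", 0)),
        )


def ranks_from_counts(counts: np.ndarray) -> np.ndarray:
    """Dense 1-based ranks by descending count.

    Ties are broken toward the smaller word value, giving a deterministic
    full permutation; zero-count words simply occupy the worst ranks.
    Accepts integer counts or real-valued frequencies.
    """
    counts = np.asarray(counts)
    # lexsort: last key is primary -> sort by -count, then by word value
    order = np.lexsort((np.arange(counts.size), -counts))
    ranks = np.empty(counts.size, dtype=np.int64)
    ranks[order] = np.arange(1, counts.size + 1)
    return ranks


def reduce_binary(signal: ECGSignal, params: RBPParams) -> BinarySequence:
    """Reduce a signal to bits: 1 where the next strided sample exceeds the
    previous one by more than ``beta``, else 0.

    With stride ``alpha`` the comparison runs along the sub-sampled series
    ``x[0], x[alpha], x[2*alpha], ...`` so bit ``t`` is
    ``x[alpha*t] > beta + x[alpha*(t-1)]`` (0-based).  With ``alpha=1`` and
    ``beta=0`` this is the plain consecutive-sample comparison and yields
    exactly ``N - 1`` bits.
    """
    x = signal.samples
    alpha = int(params.alpha)
    if x.size < alpha + 1:
        raise ValueError(
            f"signal too short: need at least alpha + 1 = {alpha + 1} samples, "
            f"got {x.size}"
        )
    sub = x[::alpha]
    bits = (sub[1:] > params.beta + sub[:-1]).astype(np.uint8)
    return BinarySequence(bits=bits, source_length=x.size, alpha_used=alpha)


def words_from_bits(bits: BinarySequence, m: int) -> WordSequence:
    """Slide an m-bit window (stride 1) over the bits; the earliest bit of
    each window is the most significant, so ``0001 -> 1`` and ``0111 -> 7``.
    """
    b = bits.bits
    if b.size < m:
        raise ValueError(
            f"insufficient bits: need at least m = {m}, got {b.size}"
        )
    weights = 1 << np.arange(m - 1, -1, -1, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(b, m)
    words = windows.astype(np.int64) @ weights
    return WordSequence(words=words, m=m)


def count_and_rank(words: WordSequence) -> RankProfile:
    """Histogram the word values and rank them by descending frequency."""
    if len(words) == 0:
        raise ValueError("empty profile: no words to count")
    counts = np.bincount(words.words, minlength=1 << words.m)
    return RankProfile.from_counts(counts, words.m)


def profile_signal(signal: ECGSignal, params: RBPParams) -> RankProfile:
    """Reduce, word-ify and rank a signal in one call."""
    return count_and_rank(words_from_bits(reduce_binary(signal, params), params.m))
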