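"""Rank-weighted distance between segments and segment groups.

The segment distance weights rank differences by the product of relative
frequencies and normalises so results stay inside [0, 1]; the group
distance is the plain mean over the cartesian product of two segment sets.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .core import ECGSignal, RBPParams, RankProfile, profile_signal

__all__ = [
    "SegmentSet",
    "DistanceMatrix",
    "segment_distance",
    "group_distance",
    "pairwise_matrix",
]


@dataclass
class SegmentSet:
    """Ordered fixed-duration segments from one subject/record."""

    segments: List[ECGSignal]
    subject_id: Optional[str] = None
    segment_seconds: float = 10.0
    fs: float = 0.0

    def __post_init__(self) -> None:
        if self.segments:
            fss = {s.fs for s in self.segments}
            if len(fss) > 1:
                raise ValueError("all segments must share one sampling rate")
            if not self.fs:
                self.fs = self.segments[0].fs

    def __len__(self) -> int:
        return len(self.segments)

    def profiles(self, params: RBPParams) -> List[RankProfile]:
        return [profile_signal(s, params) for s in self.segments]


@dataclass
class DistanceMatrix:
    """Labelled matrix of pairwise distances in [0, 1]."""

    row_labels: List[str]
    col_labels: List[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("matrix shape does not match labels")
        self.values = values

    @property
    def is_square(self) -> bool:
        return self.row_labels == self.col_labels

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow([""] + list(self.col_labels))
            for label, row in zip(self.row_labels, self.values):
                writer.writerow([label] + [f"{v:.9f}" for v in row])

    def to_dict(self) -> dict:
        return {
            "row_labels": list(self.row_labels),
            "col_labels": list(self.col_labels),
            "values": self.values.tolist(),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def segment_distance(p1: RankProfile, p2: RankProfile) -> float:
    """Weighted rank distance between two profiles.

    Sum of |R1(j) - R2(j)| * p1(j) * p2(j) over all word values, divided by
    (2**m - 1) * sum of p1(j) * p2(j).  Symmetric, zero for identical
    profiles, and bounded by 1.  Disjoint supports (zero denominator) are
    reported as maximal dissimilarity 1.0 with a warning.
    """
    if p1.m != p2.m:
        raise ValueError(f"profile mismatch: m = {p1.m} vs {p2.m}")
    weight = p1.freqs * p2.freqs
    denom_inner = weight.sum()
    if denom_inner == 0.0:
        warnings.warn(
            "profiles have disjoint word supports; returning maximal distance 1.0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 1.0
    num = (np.abs(p1.ranks - p2.ranks) * weight).sum()
    return float(num / (((1 << p1.m) - 1) * denom_inner))


def group_distance(a: SegmentSet, b: SegmentSet, params: RBPParams) -> float:
    """Mean segment distance over the full cartesian product of two sets.

    When ``a is b`` this is the intra-group distance (its zero diagonal
    pairs included in the mean), otherwise the inter-group distance.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty group: both segment sets must be non-empty")
    pa = a.profiles(params)
    pb = pa if b is a else b.profiles(params)
    return _group_distance_profiles(pa, pb)


def _group_distance_profiles(pa: Sequence[RankProfile],
                             pb: Sequence[RankProfile]) -> float:
    total = 0.0
    for p in pa:
        for q in pb:
            total += segment_distance(p, q)
    return total / (len(pa) * len(pb))


def pairwise_matrix(sets: Sequence[SegmentSet], params: RBPParams) -> DistanceMatrix:
    """Square matrix of group distances over all ordered pairs of sets."""
    if not sets:
        raise ValueError("empty group: need at least one segment set")
    labels = [
        s.subject_id if s.subject_id is not None else f"set{i}"
        for i, s in enumerate(sets)
    ]
    profiles = [s.profiles(params) for s in sets]
    n = len(sets)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            d = _group_distance_profiles(profiles[i], profiles[j])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(row_labels=labels, col_labels=list(labels), values=values)
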