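"""Verification scoring: subject-pair success rate and FA/FR metrics.

The success rate counts an ordered subject pair (L, K) as an error when the
inter-group distance D(L, K) is not larger than the row subject's own
intra-group distance D(L, L) — subjects should be closer to themselves than
to anyone else.  FA/FR thresholding accepts a claim when the distance is at
or below the threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .similarity import DistanceMatrix

__all__ = [
    "VerificationReport",
    "success_rate",
    "fa_fr",
    "tune_threshold",
    "genuine_impostor_scores",
]


@dataclass
class VerificationReport:
    """Summary of one verification experiment."""

    success_rate: float
    total_errors: int
    total_comparisons: int
    fa: float
    fr: float
    threshold: float
    per_pair: Optional[DistanceMatrix] = None

    def to_dict(self) -> dict:
        d = {
            "success_rate": self.success_rate,
            "total_errors": self.total_errors,
            "total_comparisons": self.total_comparisons,
            "fa": self.fa,
            "fr": self.fr,
            "threshold": self.threshold,
        }
        if self.per_pair is not None:
            d["per_pair"] = self.per_pair.to_dict()
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def success_rate(matrix: DistanceMatrix, baseline: str = "row") -> Tuple[int, float]:
    """Count pair errors in a square group-distance matrix.

    For every ordered pair (L, K) with L != K an error is recorded when the
    inter distance is <= the baseline intra distance (``row``: D(L, L);
    ``col``: D(K, K); ``both``: either).  Returns (errors, rate) with
    rate = 1 - errors / (n * (n - 1)).
    """
    values = matrix.values
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("matrix not square")
    if baseline not in ("row", "col", "both"):
        raise ValueError("baseline must be 'row', 'col' or 'both'")
    n = values.shape[0]
    if n < 2:
        raise ValueError("need at least two subjects to compare")
    diag = np.diag(values)
    errors = 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if baseline == "row":
                bad = values[i, j] <= diag[i]
            elif baseline == "col":
                bad = values[i, j] <= diag[j]
            else:
                bad = values[i, j] <= diag[i] or values[i, j] <= diag[j]
            errors += bool(bad)
    comparisons = n * (n - 1)
    return errors, 1.0 - errors / comparisons


def fa_fr(genuine: Sequence[float], impostor: Sequence[float],
          threshold: float) -> Tuple[float, float]:
    """False-acceptance and false-rejection rates at a threshold.

    A claim is accepted when its distance is <= threshold.  FA is the
    fraction of impostor distances accepted; FR the fraction of genuine
    distances rejected.
    """
    genuine = np.asarray(genuine, dtype=float)
    impostor = np.asarray(impostor, dtype=float)
    if genuine.size == 0 or impostor.size == 0:
        raise ValueError("no scores: genuine and impostor lists must be non-empty")
    fa = float(np.mean(impostor <= threshold))
    fr = float(np.mean(genuine > threshold))
    return fa, fr


def tune_threshold(genuine: Sequence[float],
                   impostor: Sequence[float]) -> Tuple[float, float, float]:
    """Pick the threshold minimising (FA + FR) / 2.

    Candidates are the midpoints between adjacent values of the pooled
    sorted score list plus one point below the minimum and one above the
    maximum; ties go to the smaller threshold.  Returns
    (threshold, fa, fr) at the optimum.
    """
    genuine = np.asarray(genuine, dtype=float)
    impostor = np.asarray(impostor, dtype=float)
    if genuine.size == 0 or impostor.size == 0:
        raise ValueError("no scores: genuine and impostor lists must be non-empty")
    pooled = np.unique(np.concatenate([genuine, impostor]))
    candidates = [pooled[0] - 1.0]
    candidates.extend((pooled[:-1] + pooled[1:]) / 2.0)
    candidates.append(pooled[-1] + 1.0)
    best = None
    for thr in candidates:
        fa, fr = fa_fr(genuine, impostor, thr)
        obj = (fa + fr) / 2.0
        if best is None or obj < best[0] - 1e-15:
            best = (obj, thr, fa, fr)
    _, thr, fa, fr = best
    return float(thr), fa, fr


def genuine_impostor_scores(matrix: DistanceMatrix) -> Tuple[List[float], List[float]]:
    """Split a square group-distance matrix into genuine (diagonal) and
    impostor (upper-triangle off-diagonal) score lists."""
    values = matrix.values
    if values.shape[0] != values.shape[1]:
        raise ValueError("matrix not square")
    n = values.shape[0]
    genuine = [float(values[i, i]) for i in range(n)]
    impostor = [float(values[i, j]) for i in range(n) for j in range(i + 1, n)]
    return genuine, impostor
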