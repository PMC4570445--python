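"""Experiment drivers shared by the CLI and the acceptance script.

These tie the primitives into the standard workflows: load a directory of
records as one segment set per subject, run the pairwise verification
evaluation, and measure segment-to-segment stability within one record.
"""

from __future__ import annotations

import os
from typing import List, Optional

import numpy as np

from .core import ECGSignal, RBPParams, profile_signal
from .evaluation import VerificationReport, genuine_impostor_scores, success_rate, tune_threshold
from .io import RecordSource, load_record, segment
from .similarity import SegmentSet, pairwise_matrix, segment_distance
from .synthetic import generate, sample_subject

__all__ = [
    "load_database_sets",
    "synthetic_sets",
    "evaluate_sets",
    "consecutive_segment_distances",
]


def load_database_sets(database_dir: str, fmt: str, fs: Optional[float] = None,
                       channel: int = 0, segment_seconds: float = 10.0,
                       n_segments: int = 8) -> List[SegmentSet]:
    """One SegmentSet per record file found in ``database_dir``.

    WFDB records are ``*.hea`` header files; CSV records are ``*.csv``.
    Records are ordered by name so runs are reproducible.
    """
    if fmt == "wfdb":
        names = sorted(f[:-4] for f in os.listdir(database_dir) if f.endswith(".hea"))
    elif fmt == "csv":
        names = sorted(f for f in os.listdir(database_dir) if f.endswith(".csv"))
    else:
        raise ValueError("database loading supports fmt 'csv' or 'wfdb'")
    if not names:
        raise FileNotFoundError(f"no {fmt} records found in {database_dir}")
    sets = []
    for name in names:
        path = os.path.join(database_dir, name)
        sig = load_record(RecordSource(path=path, fmt=fmt, channel=channel, fs=fs))
        seg = segment(sig, segment_seconds, n_segments)
        seg.subject_id = sig.record_id
        sets.append(seg)
    return sets


def synthetic_sets(n_subjects: int, seed: int, fs: float = 360.0,
                   segment_seconds: float = 10.0,
                   n_segments: int = 8) -> List[SegmentSet]:
    """Generate one multi-segment set per synthetic subject, seeded."""
    sets = []
    duration = segment_seconds * n_segments
    for i in range(n_subjects):
        subject_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0])
        template = sample_subject(subject_seed)
        sig = generate(template, duration_s=duration, fs=fs, seed=subject_seed)
        sig = ECGSignal(samples=sig.samples, fs=fs, subject_id=f"synth{i:02d}")
        sets.append(segment(sig, segment_seconds, n_segments))
    return sets


def evaluate_sets(sets: List[SegmentSet], params: RBPParams,
                  baseline: str = "row") -> VerificationReport:
    """Pairwise verification: success rate plus tuned-threshold FA/FR."""
    matrix = pairwise_matrix(sets, params)
    errors, rate = success_rate(matrix, baseline=baseline)
    genuine, impostor = genuine_impostor_scores(matrix)
    threshold, fa, fr = tune_threshold(genuine, impostor)
    n = len(sets)
    return VerificationReport(
        success_rate=rate, total_errors=errors, total_comparisons=n * (n - 1),
        fa=fa, fr=fr, threshold=threshold, per_pair=matrix,
    )


def consecutive_segment_distances(signal: ECGSignal, params: RBPParams,
                                  n_segments: int = 31,
                                  segment_seconds: float = 10.0) -> List[float]:
    """Distances between each consecutive pair among the first n segments
    of one record (n - 1 values); a within-subject stability measure."""
    seg = segment(signal, segment_seconds, n_segments)
    if len(seg) < n_segments:
        raise ValueError(
            f"record provides only {len(seg)} of {n_segments} segments"
        )
    profiles = [profile_signal(s, params) for s in seg.segments]
    return [segment_distance(profiles[i], profiles[i + 1])
            for i in range(len(profiles) - 1)]
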