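"""Record loading (WFDB, plain CSV, synthetic) and segmentation."""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import wfdb_min
from .core import ECGSignal
from .similarity import SegmentSet

__all__ = ["RecordSource", "load_record", "load_csv", "load_wfdb", "segment"]

_FORMATS = ("wfdb", "csv", "synthetic")


@dataclass
class RecordSource:
    """Pointer to one ECG record.

    ``path`` is a file path (csv), a record path without extension (wfdb),
    or a ``seed[:duration_s[:fs]]`` spec (synthetic).  ``fs`` is required
    for csv input since the file carries no rate.
    """

    path: str
    fmt: str = "csv"
    channel: int = 0
    fs: Optional[float] = None

    def __post_init__(self) -> None:
        if self.fmt not in _FORMATS:
            raise ValueError(f"unknown format {self.fmt!r}; supported: {_FORMATS}")


def load_csv(path: str, fs: float, channel: int = 0) -> ECGSignal:
    """One-column (or delimited multi-column) numeric text; an optional
    single non-numeric header line is skipped.  Values pass through
    unmodified — no filtering, no mean removal."""
    if fs is None or not fs > 0:
        raise ValueError("missing fs for CSV input (must be > 0)")
    if not os.path.exists(path):
        raise FileNotFoundError(f"missing file: {path}")
    with open(path) as fh:
        first = fh.readline()
    skip = 0
    try:
        [float(tok) for tok in first.replace(",", " ").split()]
    except ValueError:
        skip = 1
    data = np.loadtxt(path, delimiter="," if "," in first else None,
                      skiprows=skip, ndmin=2)
    if channel >= data.shape[1]:
        raise ValueError(
            f"unknown channel {channel}: file has columns 0..{data.shape[1] - 1}"
        )
    return ECGSignal(samples=data[:, channel], fs=fs,
                     record_id=os.path.splitext(os.path.basename(path))[0])


def load_wfdb(record_path: str, channel: int = 0) -> ECGSignal:
    signals, fs, header = wfdb_min.read_record(record_path)
    if channel >= signals.shape[1]:
        raise ValueError(
            f"unknown channel {channel}: record has channels "
            f"{list(range(signals.shape[1]))} ({header.signal_names})"
        )
    return ECGSignal(samples=signals[:, channel], fs=fs,
                     record_id=header.record_name)


def load_record(source: RecordSource) -> ECGSignal:
    """Load one record according to its format tag."""
    if source.fmt == "csv":
        return load_csv(source.path, fs=source.fs, channel=source.channel)
    if source.fmt == "wfdb":
        return load_wfdb(source.path, channel=source.channel)
    # synthetic: "seed[:duration_s[:fs]]"
    from .synthetic import generate, sample_subject

    parts = source.path.split(":")
    seed = int(parts[0])
    duration = float(parts[1]) if len(parts) > 1 else 80.0
    fs = float(parts[2]) if len(parts) > 2 else (source.fs or 360.0)
    template = sample_subject(seed)
    sig = generate(template, duration_s=duration, fs=fs, seed=seed)
    return ECGSignal(samples=sig.samples, fs=sig.fs, subject_id=f"synth{seed}",
                     record_id=source.path)


def segment(signal: ECGSignal, segment_seconds: float = 10.0,
            max_segments: Optional[int] = None) -> SegmentSet:
    """Cut a signal into consecutive non-overlapping fixed-length windows.

    Window length is ``round(segment_seconds * fs)`` samples; the trailing
    partial window is dropped; at most ``max_segments`` are returned when
    given.  Sample values are never altered.
    """
    win = int(round(segment_seconds * signal.fs))
    if win < 2:
        raise ValueError("segment_seconds too small for this sampling rate")
    n = len(signal) // win
    if n == 0:
        raise ValueError(
            f"signal shorter than one segment: need {win} samples, got {len(signal)}"
        )
    if max_segments is not None:
        n = min(n, max_segments)
    segments = [
        ECGSignal(samples=signal.samples[i * win:(i + 1) * win], fs=signal.fs,
                  subject_id=signal.subject_id, record_id=signal.record_id)
        for i in range(n)
    ]
    return SegmentSet(segments=segments, subject_id=signal.subject_id,
                      segment_seconds=segment_seconds, fs=signal.fs)
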