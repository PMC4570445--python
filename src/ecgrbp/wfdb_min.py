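"""Minimal WFDB record support (PhysioNet header + signal file layout).

Reads the subset of the format the MIT-BIH databases use: a ``.hea``
header naming one signal file shared by all channels, with samples stored
in format 212 (two 12-bit two's-complement samples packed into 3 bytes) or
format 16 (little-endian int16), one sample per signal per frame.  Raw ADC
values are returned unconverted.  A matching writer exists so round-trips
can be tested without network access.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

__all__ = ["WFDBHeader", "read_header", "read_record", "write_record"]

_SUPPORTED_FORMATS = ("212", "16")


@dataclass
class WFDBHeader:
    record_name: str
    n_sig: int
    fs: float
    n_samples: int
    file_names: List[str]
    formats: List[str]
    signal_names: List[str]


def read_header(hea_path: str) -> WFDBHeader:
    with open(hea_path) as fh:
        lines = [ln.strip() for ln in fh
                 if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"empty WFDB header: {hea_path}")
    head = lines[0].split()
    record_name = head[0].split("/")[0]
    n_sig = int(head[1])
    fs = float(head[2].split("/")[0]) if len(head) > 2 else 250.0
    n_samples = int(head[3]) if len(head) > 3 else 0
    file_names, formats, signal_names = [], [], []
    for i, line in enumerate(lines[1:1 + n_sig]):
        parts = line.split()
        file_names.append(parts[0])
        fmt = re.match(r"(\d+)", parts[1])
        if fmt is None:
            raise ValueError(f"unparseable signal format field: {parts[1]!r}")
        formats.append(fmt.group(1))
        signal_names.append(parts[-1] if len(parts) > 2 else f"sig{i}")
    if len(file_names) != n_sig:
        raise ValueError(f"header lists {len(file_names)} signals, expected {n_sig}")
    return WFDBHeader(record_name, n_sig, fs, n_samples,
                      file_names, formats, signal_names)


def _decode_212(raw: np.ndarray, n_values: int) -> np.ndarray:
    raw = raw[: (raw.size // 3) * 3].reshape(-1, 3).astype(np.int32)
    s0 = ((raw[:, 1] & 0x0F) << 8) | raw[:, 0]
    s1 = ((raw[:, 1] & 0xF0) << 4) | raw[:, 2]
    values = np.empty(raw.shape[0] * 2, dtype=np.int32)
    values[0::2] = s0
    values[1::2] = s1
    values[values > 2047] -= 4096
    return values[:n_values]


def _encode_212(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=np.int32)
    if values.min() < -2048 or values.max() > 2047:
        raise ValueError("format 212 stores 12-bit values in [-2048, 2047]")
    if values.size % 2:
        values = np.concatenate([values, [0]])
    v = np.where(values < 0, values + 4096, values)
    s0, s1 = v[0::2], v[1::2]
    raw = np.empty((s0.size, 3), dtype=np.uint8)
    raw[:, 0] = s0 & 0xFF
    raw[:, 1] = ((s0 >> 8) & 0x0F) | (((s1 >> 8) & 0x0F) << 4)
    raw[:, 2] = s1 & 0xFF
    return raw.reshape(-1)


def read_record(record_path: str) -> Tuple[np.ndarray, float, WFDBHeader]:
    """Read ``<record_path>.hea`` + signal file(s).

    Returns (signals, fs, header) where signals has shape
    (n_samples, n_sig) and holds raw ADC integers as floats.
    """
    if record_path.endswith(".hea"):
        record_path = record_path[:-4]
    hea_path = record_path + ".hea"
    if not os.path.exists(hea_path):
        raise FileNotFoundError(f"missing WFDB header: {hea_path}")
    header = read_header(hea_path)
    base_dir = os.path.dirname(os.path.abspath(hea_path))
    if len(set(header.file_names)) != 1:
        raise ValueError("multi-file WFDB records are not supported")
    fmt = header.formats[0]
    if any(f != fmt for f in header.formats):
        raise ValueError("mixed per-signal formats are not supported")
    if fmt not in _SUPPORTED_FORMATS:
        raise ValueError(
            f"unsupported WFDB signal format {fmt}; supported: {_SUPPORTED_FORMATS}"
        )
    dat_path = os.path.join(base_dir, header.file_names[0])
    if not os.path.exists(dat_path):
        raise FileNotFoundError(f"missing WFDB signal file: {dat_path}")
    raw = np.fromfile(dat_path, dtype=np.uint8)
    n_values = header.n_samples * header.n_sig if header.n_samples else None
    if fmt == "212":
        if n_values is None:
            n_values = (raw.size // 3) * 2
        values = _decode_212(raw, n_values)
    else:  # format 16
        values = raw[: (raw.size // 2) * 2].view("<i2").astype(np.int32)
        if n_values is not None:
            values = values[:n_values]
    n_frames = values.size // header.n_sig
    signals = values[: n_frames * header.n_sig].reshape(n_frames, header.n_sig)
    return signals.astype(float), header.fs, header


def write_record(directory: str, record_name: str, signals: np.ndarray,
                 fs: float, fmt: str = "212",
                 signal_names: List[str] | None = None) -> str:
    """Write a header/signal pair; returns the record path (no extension)."""
    signals = np.atleast_2d(np.asarray(signals))
    if signals.shape[0] < signals.shape[1]:  # accept (n_sig, n) input
        signals = signals.T
    n_samples, n_sig = signals.shape
    if fmt not in _SUPPORTED_FORMATS:
        raise ValueError(f"unsupported WFDB signal format {fmt}")
    if signal_names is None:
        signal_names = [f"sig{i}" for i in range(n_sig)]
    interleaved = np.rint(signals).astype(np.int32).reshape(-1)
    dat_name = f"{record_name}.dat"
    if fmt == "212":
        raw = _encode_212(interleaved)
    else:
        raw = interleaved.astype("<i2").tobytes()
        raw = np.frombuffer(raw, dtype=np.uint8)
    os.makedirs(directory, exist_ok=True)
    raw.tofile(os.path.join(directory, dat_name))
    fs_str = f"{fs:g}"
    lines = [f"{record_name} {n_sig} {fs_str} {n_samples}"]
    for i in range(n_sig):
        first = int(np.rint(signals[0, i]))
        lines.append(f"{dat_name} {fmt} 200 11 1024 {first} 0 0 {signal_names[i]}")
    with open(os.path.join(directory, f"{record_name}.hea"), "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return os.path.join(directory, record_name)
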