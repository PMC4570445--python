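"""Seeded multi-subject synthetic single-lead ECG.

Each subject is a template of five Gaussian bumps (P, Q, R, S, T) placed at
per-subject fractions of the beat, plus a mean heart rate, beat-to-beat
variability, and additive white noise.  Amplitudes are on an ADC-count-like
scale (hundreds of units for the R wave) so amplitude thresholds of a few
units behave as they would on raw 11/12-bit recordings.  Everything is
deterministic given (template, seed).
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, replace
from typing import Dict, List, Tuple

import numpy as np

from .core import ECGSignal

__all__ = [
    "WAVES",
    "SubjectTemplate",
    "sample_subject",
    "generate",
    "generate_sessions",
]

WAVES = ("P", "Q", "R", "S", "T")

# Per-wave sampling ranges: amplitude (ADC counts), centre (fraction of the
# beat) and width (fraction of the beat).  These ranges are the fixture
# contract: every template drawn by sample_subject stays inside them.
TEMPLATE_RANGES: Dict[str, Dict[str, Tuple[float, float]]] = {
    "P": {"amplitude": (15.0, 60.0), "center": (0.10, 0.20), "width": (0.020, 0.045)},
    "Q": {"amplitude": (-70.0, -15.0), "center": (0.26, 0.30), "width": (0.006, 0.014)},
    "R": {"amplitude": (150.0, 380.0), "center": (0.30, 0.34), "width": (0.008, 0.018)},
    "S": {"amplitude": (-110.0, -20.0), "center": (0.34, 0.38), "width": (0.006, 0.016)},
    "T": {"amplitude": (40.0, 130.0), "center": (0.52, 0.66), "width": (0.040, 0.090)},
}
BPM_RANGE = (52.0, 98.0)
HRV_STD_RANGE = (0.01, 0.05)       # std of beat-to-beat interval, seconds
NOISE_STD_RANGE = (2.0, 7.0)       # ADC counts


@dataclass(frozen=True)
class SubjectTemplate:
    """Morphology + rhythm parameters of one synthetic subject."""

    amplitudes: Dict[str, float]
    centers: Dict[str, float]
    widths: Dict[str, float]
    mean_bpm: float
    hrv_std: float
    noise_std: float
    drift_rate: float = 0.0

    def __post_init__(self) -> None:
        for wave in WAVES:
            if self.widths[wave] <= 0:
                raise ValueError(f"width of {wave} must be positive")
        if not 30.0 < self.mean_bpm < 220.0:
            raise ValueError("mean heart rate must be in (30, 220) bpm")
        if self.noise_std < 0:
            raise ValueError("noise std must be >= 0")

    def drifted(self, k: int) -> "SubjectTemplate":
        """Template after ``k`` sessions of cumulative fractional drift."""
        f = 1.0 + self.drift_rate * k
        return replace(
            self,
            amplitudes={w: a * f for w, a in self.amplitudes.items()},
            mean_bpm=min(max(self.mean_bpm * (1.0 + 0.5 * self.drift_rate * k),
                             31.0), 219.0),
            noise_std=self.noise_std * f,
        )


def sample_subject(seed: int, drift_rate: float = 0.0) -> SubjectTemplate:
    """Draw a subject template from the documented ranges, deterministically."""
    rng = np.random.default_rng(seed)
    amplitudes, centers, widths = {}, {}, {}
    for wave in WAVES:
        r = TEMPLATE_RANGES[wave]
        amplitudes[wave] = float(rng.uniform(*r["amplitude"]))
        centers[wave] = float(rng.uniform(*r["center"]))
        widths[wave] = float(rng.uniform(*r["width"]))
    return SubjectTemplate(
        amplitudes=amplitudes,
        centers=centers,
        widths=widths,
        mean_bpm=float(rng.uniform(*BPM_RANGE)),
        hrv_std=float(rng.uniform(*HRV_STD_RANGE)),
        noise_std=float(rng.uniform(*NOISE_STD_RANGE)),
        drift_rate=drift_rate,
    )


def generate(template: SubjectTemplate, duration_s: float, fs: float,
             seed: int) -> ECGSignal:
    """Render a quasi-periodic trace from a template.

    Beat onsets advance by the mean interval plus Gaussian jitter of the
    template's variability; each beat contributes five Gaussian bumps
    scaled to its own length; white noise is added on top.
    """
    if not duration_s > 0 or not fs > 0:
        raise ValueError("duration_s and fs must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    signal = np.zeros(n)
    mean_rr = 60.0 / template.mean_bpm

    onset = 0.0
    while onset < duration_s:
        rr = mean_rr + (rng.normal(0.0, template.hrv_std) if template.hrv_std else 0.0)
        rr = max(rr, 0.25)
        for wave in WAVES:
            mu = onset + template.centers[wave] * rr
            sigma = template.widths[wave] * rr
            lo = max(int((mu - 5 * sigma) * fs), 0)
            hi = min(int((mu + 5 * sigma) * fs) + 1, n)
            if lo < hi:
                window = t[lo:hi]
                signal[lo:hi] += template.amplitudes[wave] * np.exp(
                    -0.5 * ((window - mu) / sigma) ** 2
                )
        onset += rr

    if template.noise_std > 0:
        signal += rng.normal(0.0, template.noise_std, n)
    return ECGSignal(samples=signal, fs=fs)


def generate_sessions(template: SubjectTemplate, n_sessions: int,
                      records_per_session: int, drift_rate: float, seed: int,
                      fs: float = 360.0, record_seconds: float = 20.0,
                      start_date: str = "2025-01-01",
                      subject_id: str | None = None) -> List[ECGSignal]:
    """Dated multi-session records with optional cumulative parameter drift.

    Session ``k`` uses the template drifted by ``k`` steps; each record gets
    its own sub-seed and a synthetic date one week per session after
    ``start_date``.
    """
    if n_sessions < 1:
        raise ValueError("need at least one session")
    base = datetime.date.fromisoformat(start_date)
    template = replace(template, drift_rate=drift_rate)
    records: List[ECGSignal] = []
    for k in range(n_sessions):
        session_template = template.drifted(k)
        date = (base + datetime.timedelta(days=7 * k)).isoformat()
        for r in range(records_per_session):
            sub_seed = int(np.random.SeedSequence([seed, k, r]).generate_state(1)[0])
            sig = generate(session_template, duration_s=record_seconds,
                           fs=fs, seed=sub_seed)
            records.append(ECGSignal(
                samples=sig.samples, fs=fs,
                subject_id=subject_id,
                record_id=f"s{k:02d}r{r:02d}",
                timestamp=date,
            ))
    return records
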