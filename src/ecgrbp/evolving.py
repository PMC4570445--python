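"""Incrementally updated per-subject rank models for long-term ECG.

A subject's model is a frequency vector blended with each new recording at
weight gamma; ranks are recomputed from the blended frequencies.  The
long-term protocol replays dated recordings: on each day the first valid
record updates the model, the rest are scored against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import ECGSignal, RBPParams, RankProfile, profile_signal, ranks_from_counts
from .similarity import segment_distance

__all__ = [
    "EvolvingModel",
    "LongtermReport",
    "record_profile",
    "update_model",
    "run_longterm_protocol",
]


@dataclass
class EvolvingModel:
    """Per-subject model state: blended frequencies plus their ranks.

    After the first blend the model's counts are no longer meaningful;
    ``profile.freqs``/``profile.ranks`` are the authoritative state.
    """

    subject_id: Optional[str]
    profile: RankProfile
    gamma: float
    params: RBPParams
    update_log: List[Tuple[Optional[str], Optional[str]]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "m": self.params.m,
            "alpha": self.params.alpha,
            "beta": self.params.beta,
            "gamma": self.gamma,
            "freqs": self.profile.freqs.tolist(),
            "ranks": self.profile.ranks.tolist(),
            "update_log": [list(entry) for entry in self.update_log],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def record_profile(record: ECGSignal, params: RBPParams,
                   segment_seconds: float = 10.0) -> RankProfile:
    """Profile a recording as the mean of its two half-length segments.

    The record is split into two equal halves, each half is profiled, the
    two relative-frequency vectors are averaged and renormalised, and ranks
    are recomputed with the standard tie rule.
    """
    needed = int(round(2 * segment_seconds * record.fs))
    if len(record) < needed:
        raise ValueError(
            f"record too short: need at least {needed} samples "
            f"(2 x {segment_seconds} s at {record.fs} Hz), got {len(record)}"
        )
    half = len(record) // 2
    first = ECGSignal(record.samples[:half], record.fs)
    second = ECGSignal(record.samples[half:2 * half], record.fs)
    p1 = profile_signal(first, params)
    p2 = profile_signal(second, params)
    mean_freqs = (p1.freqs + p2.freqs) / 2.0
    return RankProfile.from_freqs(mean_freqs, params.m)


def update_model(model: EvolvingModel, new_profile: RankProfile,
                 record_id: Optional[str] = None,
                 timestamp: Optional[str] = None) -> EvolvingModel:
    """Blend a new profile into the model at weight gamma.

    Frequencies become (1 - gamma) * p + gamma * p_new; ranks are
    recomputed from the blend.  Returns a new model; the input is left
    untouched.
    """
    if model.profile.m != new_profile.m:
        raise ValueError(
            f"profile mismatch: m = {model.profile.m} vs {new_profile.m}"
        )
    g = model.gamma
    # exact limits: no renormalisation noise at the identity/replacement ends
    if g == 0.0:
        profile = model.profile
    elif g == 1.0:
        profile = RankProfile(m=new_profile.m, freqs=new_profile.freqs,
                              ranks=new_profile.ranks)
    else:
        blended = (1.0 - g) * model.profile.freqs + g * new_profile.freqs
        profile = RankProfile.from_freqs(blended, model.profile.m)
    return EvolvingModel(
        subject_id=model.subject_id,
        profile=profile,
        gamma=g,
        params=model.params,
        update_log=model.update_log + [(timestamp, record_id)],
    )


@dataclass
class LongtermReport:
    """Replay of the daily update protocol for one subject.

    ``entries`` holds one (date, record_id, evolving_distance,
    static_distance, updated) tuple per scored record, in chronological
    order.  ``s_evolving``/``s_static`` sum the distances of records that
    were never absorbed, counted only after the first update point;
    ``improvement`` is their relative gap, or None when no such records
    exist.
    """

    subject_id: Optional[str]
    gamma: float
    entries: List[Tuple[str, Optional[str], float, float, bool]]
    s_evolving: float
    s_static: float
    improvement: Optional[float]

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "gamma": self.gamma,
            "entries": [
                {
                    "date": date,
                    "record_id": rid,
                    "evolving_distance": dev,
                    "static_distance": dst,
                    "updated": updated,
                }
                for date, rid, dev, dst, updated in self.entries
            ],
            "s_evolving": self.s_evolving,
            "s_static": self.s_static,
            "improvement": self.improvement,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _date_key(record: ECGSignal) -> str:
    if record.timestamp is None:
        raise ValueError("empty history: records must carry timestamps")
    return str(record.timestamp)[:10]


def run_longterm_protocol(records: Sequence[ECGSignal], model_gamma: float,
                          params: RBPParams,
                          segment_seconds: float = 10.0) -> LongtermReport:
    """Replay dated records through the daily-update protocol.

    The model is initialised from the first record of the first day.  On
    every later day each record is scored against the current model (and
    against the frozen initial model for the non-evolving reference); the
    day's first record is then absorbed at weight gamma.  Distances of the
    never-absorbed records from the second day onward are summed for both
    variants and compared.
    """
    if not records:
        raise ValueError("empty history: no records given")
    ordered = sorted(records, key=lambda r: (str(r.timestamp), str(r.record_id)))
    days: List[Tuple[str, List[ECGSignal]]] = []
    for rec in ordered:
        day = _date_key(rec)
        if days and days[-1][0] == day:
            days[-1][1].append(rec)
        else:
            days.append((day, [rec]))

    first_day, first_records = days[0]
    initial_profile = record_profile(first_records[0], params, segment_seconds)
    model = EvolvingModel(
        subject_id=first_records[0].subject_id,
        profile=initial_profile,
        gamma=model_gamma,
        params=params,
        update_log=[(first_records[0].timestamp, first_records[0].record_id)],
    )

    entries: List[Tuple[str, Optional[str], float, float, bool]] = []
    s_evolving = 0.0
    s_static = 0.0

    # remaining first-day records are scored but precede any update point
    for rec in first_records[1:]:
        rp = record_profile(rec, params, segment_seconds)
        d = segment_distance(model.profile, rp)
        d0 = segment_distance(initial_profile, rp)
        entries.append((first_day, rec.record_id, d, d0, False))

    for day, day_records in days[1:]:
        for idx, rec in enumerate(day_records):
            rp = record_profile(rec, params, segment_seconds)
            d_ev = segment_distance(model.profile, rp)
            d_st = segment_distance(initial_profile, rp)
            is_update = idx == 0
            entries.append((day, rec.record_id, d_ev, d_st, is_update))
            if is_update:
                model = update_model(model, rp, record_id=rec.record_id,
                                     timestamp=rec.timestamp)
            else:
                s_evolving += d_ev
                s_static += d_st

    improvement: Optional[float]
    if s_static > 0.0:
        improvement = (s_static - s_evolving) / s_static
    else:
        improvement = None
    return LongtermReport(
        subject_id=model.subject_id,
        gamma=model_gamma,
        entries=entries,
        s_evolving=s_evolving,
        s_static=s_static,
        improvement=improvement,
    )
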