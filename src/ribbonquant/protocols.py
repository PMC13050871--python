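"""Optogenetic stimulation schedules.

Two stimulation paradigms deliver the same light dose per session:

* **oSparse** — single 5 ms pulses evenly spaced at 5 Hz (one pulse
  every 200 ms);
* **oBurst** — bursts of five 5 ms pulses at 50 Hz intra-burst rate
  (one pulse every 20 ms), one burst per 1 s epoch, rest for the
  remainder of the epoch.

Over a standard 1 h session both protocols deliver 18,000 pulses and
90 s of total on-time.  Time is represented as exact integer
microseconds internally so a 3600 s schedule accumulates no float
drift.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

__all__ = ["PulseTrain", "make_osparse", "make_oburst", "audit", "export_csv", "import_csv"]

_US = 1_000_000  # microseconds per second


@dataclass(frozen=True)
class PulseTrain:
    """An ordered light-pulse schedule.

    ``pulses_us`` holds (onset, duration) pairs in integer microseconds;
    onsets strictly increase, pulses never overlap, and every pulse ends
    within the session.  ``power_density_mw_mm2`` is metadata only.
    """

    pulses_us: tuple
    protocol_name: str
    session_duration_us: int
    power_density_mw_mm2: float | None = None

    def __post_init__(self):
        last_end = -1
        prev_onset = -1
        for onset, dur in self.pulses_us:
            if onset <= prev_onset:
                raise ValueError("pulse onsets must strictly increase")
            if onset < last_end:
                raise ValueError("pulses must not overlap")
            if onset + dur > self.session_duration_us:
                raise ValueError("pulse extends past the session end")
            prev_onset, last_end = onset, onset + dur

    @property
    def n_pulses(self) -> int:
        return len(self.pulses_us)

    def onsets_s(self):
        return [on / _US for on, _ in self.pulses_us]


def make_osparse(
    session_s: float = 3600.0,
    pulse_ms: float = 5.0,
    rate_hz: float = 5.0,
    phase_s: float = 0.0,
) -> PulseTrain:
    """Evenly spaced pulse train: onsets at phase + k / rate for
    k = 0 … rate·session − 1 (pulses past the session end are dropped)."""
    if pulse_ms <= 0 or rate_hz <= 0:
        raise ValueError("pulse duration and rate must be positive")
    if phase_s < 0:
        raise ValueError("phase must be >= 0")
    if rate_hz * pulse_ms / 1000.0 >= 1.0:
        raise ValueError("duty cycle must be below 100%")
    period_us = round(_US / rate_hz)
    dur_us = round(pulse_ms * 1000)
    phase_us = round(phase_s * _US)
    session_us = round(session_s * _US)
    n = int(rate_hz * session_s)
    pulses = tuple(
        (phase_us + k * period_us, dur_us)
        for k in range(n)
        if phase_us + k * period_us + dur_us <= session_us
    )
    return PulseTrain(pulses, "oSparse", session_us)


def make_oburst(
    session_s: float = 3600.0,
    pulse_ms: float = 5.0,
    pulses_per_burst: int = 5,
    intra_hz: float = 50.0,
    epoch_s: float = 1.0,
    phase_s: float = 0.0,
) -> PulseTrain:
    """Burst train: each epoch starts with ``pulses_per_burst`` pulses at
    the intra-burst rate, then rests until the epoch ends.  ``phase_s``
    shifts every epoch's burst; bursts shifted past their epoch raise."""
    if pulse_ms <= 0 or intra_hz <= 0 or epoch_s <= 0:
        raise ValueError("durations and rates must be positive")
    if pulses_per_burst < 0:
        raise ValueError("pulses_per_burst must be >= 0")
    intra_period_us = round(_US / intra_hz)
    dur_us = round(pulse_ms * 1000)
    if phase_s < 0:
        raise ValueError("phase must be >= 0")
    burst_span_us = (pulses_per_burst - 1) * intra_period_us + dur_us if pulses_per_burst else 0
    epoch_us = round(epoch_s * _US)
    phase_us = round(phase_s * _US)
    if phase_us + burst_span_us > epoch_us:
        raise ValueError("burst does not fit inside one epoch")
    n_epochs = int(session_s / epoch_s)
    pulses = tuple(
        (e * epoch_us + phase_us + k * intra_period_us, dur_us)
        for e in range(n_epochs)
        for k in range(pulses_per_burst)
    )
    return PulseTrain(pulses, "oBurst", round(session_s * _US))


def audit(train: PulseTrain) -> dict:
    """Exact dose bookkeeping of a schedule.

    Returns pulse count, total on-time (s), duty cycle over the session,
    and the min/max onset-to-onset interval (s; ``None`` for < 2 pulses).
    """
    onsets = [on for on, _ in train.pulses_us]
    durs = [d for _, d in train.pulses_us]
    for i in range(1, len(onsets)):
        if onsets[i] < onsets[i - 1] + durs[i - 1]:
            raise ValueError("overlapping pulses in train")
    total_on_us = sum(durs)
    session_us = train.session_duration_us
    intervals = [b - a for a, b in zip(onsets, onsets[1:])]
    return {
        "protocol": train.protocol_name,
        "n_pulses": len(onsets),
        "total_on_time_s": total_on_us / _US,
        "duty_cycle": (total_on_us / session_us) if session_us > 0 else 0.0,
        "min_onset_interval_s": min(intervals) / _US if intervals else None,
        "max_onset_interval_s": max(intervals) / _US if intervals else None,
    }


def export_csv(train: PulseTrain, path) -> None:
    """TTL-style schedule: one row per pulse, integer microseconds."""
    pd.DataFrame(train.pulses_us, columns=["onset_us", "duration_us"]).to_csv(path, index=False)
    meta = {
        "protocol_name": train.protocol_name,
        "session_duration_us": train.session_duration_us,
        "power_density_mw_mm2": train.power_density_mw_mm2,
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(meta, fh)


def import_csv(path) -> PulseTrain:
    df = pd.read_csv(path)
    with open(str(path) + ".json") as fh:
        meta = json.load(fh)
    pulses = tuple((int(o), int(d)) for o, d in zip(df["onset_us"], df["duration_us"]))
    return PulseTrain(
        pulses,
        meta["protocol_name"],
        int(meta["session_duration_us"]),
        meta["power_density_mw_mm2"],
    )
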