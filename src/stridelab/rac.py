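"""Rhythmic auditory cueing: cadence estimation and metronome schedules.

A rhythmic-auditory-cueing (RAC) session sets a metronome either at the
subject's average self-paced cadence ("100% RAC") or 10% faster ("110% RAC").
Cadence is estimated from pooled straight-walking step intervals, and the cue
schedule is a plain arithmetic sequence of beat times.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .imu_io import GaitEventSeries
from .spatiotemporal import InsufficientDataError, step_time_intervals

__all__ = ["CueSchedule", "mean_cadence", "metronome_schedule"]


@dataclass(frozen=True)
class CueSchedule:
    """A metronome schedule: beats at 0, IBI, 2*IBI, ... <= duration."""

    tempo: float  # beats per minute
    relative_tempo: float
    duration: float
    beat_times: np.ndarray

    @property
    def inter_beat_interval(self) -> float:
        return 60.0 / self.tempo

    def to_json(self) -> str:
        return json.dumps(
            {
                "tempo_bpm": self.tempo,
                "relative_tempo": self.relative_tempo,
                "inter_beat_interval_s": self.inter_beat_interval,
                "duration_s": self.duration,
                "beat_times_s": [round(float(b), 9) for b in self.beat_times],
            },
            indent=2,
        )


def mean_cadence(events: GaitEventSeries) -> float:
    """Average cadence in steps/min from pooled within-trial step intervals.

    Computed as 60 * (number of intervals) / (summed interval time) over all
    straight segments pooled together — not a per-trial average of averages.
    """
    intervals = step_time_intervals(events)
    n = sum(len(iv) for iv in intervals)
    if n < 1:
        raise InsufficientDataError("need >= 2 events in some trial to estimate cadence")
    total = float(sum(iv.sum() for iv in intervals))
    return 60.0 * n / total


def metronome_schedule(cadence: float, relative_tempo: float, duration: float) -> CueSchedule:
    """Build a cue schedule at ``relative_tempo`` times the given cadence.

    ``relative_tempo`` 1.0 reproduces the self-paced cadence; 1.1 plays 10%
    faster.  Beats start at t=0 with no count-in.
    """
    if cadence <= 0 or relative_tempo <= 0:
        raise ValueError("cadence and relative_tempo must be > 0")
    if duration < 0:
        raise ValueError("duration must be >= 0")
    tempo = cadence * relative_tempo
    ibi = 60.0 / tempo
    n_beats = int(np.floor(duration / ibi + 1e-9)) + 1
    beats = np.arange(n_beats) * ibi
    return CueSchedule(
        tempo=tempo, relative_tempo=relative_tempo, duration=duration, beat_times=beats
    )
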