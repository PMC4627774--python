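"""Heel-strike analogue detection from trunk acceleration.

The vertical (UD) trunk acceleration of a walking subject shows one dominant
positive peak per step whose timing tracks the actual heel contact measured by
a footswitch — the "heel-strike analogue".  Detection here is deliberately
simple and auditable:

1. zero-phase band-pass (Butterworth, default 0.3-8 Hz, order 4) so gravity/DC
   and high-frequency jitter are removed without shifting event timing;
2. peak picking on the filtered UD channel with a refractory period and a
   prominence floor expressed as a fraction of the robust (5th-95th
   percentile) amplitude range, so detection is invariant to offset and
   positive rescaling;
3. turn exclusion from the smoothed yaw rate, with a guard band of steps
   discarded on each side of the turn, splitting the walk into straight
   segments that downstream code treats as separate trials;
4. foot-side classification from the sign of the mean roll rate in a window
   around each event, with the sign->side polarity auto-calibrated per
   recording by an alternation vote (absolute device roll polarity depends on
   strap placement).

A greedy nearest-neighbour matcher aligns detected events with reference
device events for concurrent-validity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sp_signal

from .imu_io import BodyFrameSignal, GaitEventSeries

__all__ = [
    "DetectionParams",
    "MatchResult",
    "preprocess",
    "detect_heel_strike_analogues",
    "exclude_turn_segments",
    "classify_foot_side",
    "match_events",
]


class ParameterError(ValueError):
    """Detection parameters outside their documented domain."""


class TooShortError(ValueError):
    """Signal too short for the requested filter."""


@dataclass(frozen=True)
class DetectionParams:
    """Tunable constants of the event detector.

    band : (low, high) cutoff frequencies of the zero-phase band-pass, Hz.
    min_separation : refractory period between accepted peaks, s
        (0.25 s admits cadences up to 4 steps/s).
    prominence_frac : required peak prominence as a fraction of the filtered
        signal's 5th-95th percentile amplitude range.
    turn_yaw_threshold : |yaw rate| above which (smoothed over 0.5 s) the
        subject is considered turning, rad/s.
    turn_guard_steps : events discarded on each side of a turn window.
    """

    band: tuple[float, float] = (0.3, 8.0)
    order: int = 4
    min_separation: float = 0.25
    prominence_frac: float = 0.3
    turn_yaw_threshold: float = 0.6
    turn_guard_steps: int = 1
    roll_window: float = 0.150

    def validate(self, fs: float) -> None:
        low, high = self.band
        if not (0.0 < low < high < fs / 2.0):
            raise ParameterError(f"band {self.band} must satisfy 0 < low < high < Nyquist")
        if self.min_separation <= 0:
            raise ParameterError("min_separation must be > 0")
        if not (0.0 < self.prominence_frac <= 1.0):
            raise ParameterError("prominence_frac must lie in (0, 1]")
        if self.turn_guard_steps < 0:
            raise ParameterError("turn_guard_steps must be >= 0")


def _bandpass_sos(params: DetectionParams, fs: float):
    return sp_signal.butter(params.order, params.band, btype="bandpass", fs=fs, output="sos")


def preprocess(sig: BodyFrameSignal, params: DetectionParams = DetectionParams()) -> BodyFrameSignal:
    """Zero-phase band-pass all six body-frame channels.

    Removes gravity/DC (high-pass at the band's low edge) and high-frequency
    noise (low-pass at the high edge) with ``sosfiltfilt`` so that peak timing
    is not shifted by filter group delay.
    """
    params.validate(sig.fs)
    sos = _bandpass_sos(params, sig.fs)
    # sosfiltfilt needs padding room; require ~3 filter lengths of data
    min_len = 3 * (2 * params.order + 1)
    if len(sig) < min_len:
        raise TooShortError(f"signal of {len(sig)} samples is too short to filter")

    def f(x):
        return sp_signal.sosfiltfilt(sos, x)

    return BodyFrameSignal(
        t=sig.t,
        a_AP=f(sig.a_AP),
        a_UD=f(sig.a_UD),
        a_LR=f(sig.a_LR),
        w_AP=f(sig.w_AP),
        w_UD=f(sig.w_UD),
        w_LR=f(sig.w_LR),
        fs=sig.fs,
        meta=dict(sig.meta),
    )


def _detection_channel(sig: BodyFrameSignal) -> np.ndarray:
    """UD acceleration, falling back to AP when UD band power is degenerate."""
    ud, ap = sig.a_UD, sig.a_AP
    if np.std(ud) < 1e-12 and np.std(ap) > 1e-12:
        return ap
    return ud


def detect_heel_strike_analogues(
    sig: BodyFrameSignal, params: DetectionParams = DetectionParams()
) -> GaitEventSeries:
    """Pick heel-strike analogue peaks from a preprocessed body-frame signal.

    Each event is timestamped at the local-maximum sample (earliest sample of
    a plateau).  Returns an empty series when no peak satisfies the prominence
    and separation constraints.
    """
    params.validate(sig.fs)
    x = _detection_channel(sig)
    p5, p95 = np.percentile(x, [5, 95])
    amp = p95 - p5
    if amp <= 0:
        return GaitEventSeries(
            times=np.empty(0), feet=(), device="smartmove", trial=np.empty(0, dtype=int)
        )
    distance = max(1, int(round(params.min_separation * sig.fs)))
    peaks, props = sp_signal.find_peaks(
        x,
        distance=distance,
        prominence=params.prominence_frac * amp,
        plateau_size=(None, None),
    )
    # earliest sample of a plateau peak
    left_edges = props.get("left_edges")
    if left_edges is not None:
        peaks = left_edges
    times = sig.t[peaks]
    return GaitEventSeries(
        times=times,
        feet=("unknown",) * len(times),
        device="smartmove",
        trial=np.zeros(len(times), dtype=int),
    )


def _smoothed_yaw(sig: BodyFrameSignal, window_s: float = 0.5) -> np.ndarray:
    n = max(1, int(round(window_s * sig.fs)))
    kernel = np.ones(n) / n
    return np.convolve(np.abs(sig.w_UD), kernel, mode="same")


def exclude_turn_segments(
    events: GaitEventSeries,
    sig: BodyFrameSignal,
    params: DetectionParams = DetectionParams(),
) -> GaitEventSeries:
    """Drop events during turns and re-group the rest into straight segments.

    An event is "turning" when the 0.5-s-smoothed |yaw rate| at its time
    exceeds ``turn_yaw_threshold``; ``turn_guard_steps`` neighbouring events on
    each side of every turning run are discarded as well.  Surviving events are
    assigned fresh consecutive trial indices, one per straight segment, so that
    no step interval is ever computed across a turn.
    """
    params.validate(sig.fs)
    if len(events) == 0:
        return events
    yaw = _smoothed_yaw(sig)
    turning_samples = yaw > params.turn_yaw_threshold

    # contiguous turning runs -> turn time intervals
    edges = np.flatnonzero(np.diff(turning_samples.astype(int)))
    starts = list(edges[~turning_samples[edges]] + 1)
    ends = list(edges[turning_samples[edges]] + 1)
    if turning_samples[0]:
        starts.insert(0, 0)
    if turning_samples[-1]:
        ends.append(len(turning_samples))
    intervals = [(sig.t[s], sig.t[min(e, len(sig.t) - 1)]) for s, e in zip(starts, ends)]

    remove = np.zeros(len(events), dtype=bool)
    g = params.turn_guard_steps
    for t_a, t_b in intervals:
        inside = (events.times >= t_a) & (events.times <= t_b)
        remove |= inside
        if g > 0:
            before = np.flatnonzero(events.times < t_a)
            after = np.flatnonzero(events.times > t_b)
            remove[before[-g:]] = True
            remove[after[:g]] = True
    keep = ~remove

    kept = events.subset(keep)
    if len(kept) == 0:
        return kept
    # renumber trials: a straight segment ends at every removed event, turn
    # interval, or original trial boundary between consecutive kept events
    orig_idx = np.flatnonzero(keep)
    seg = np.zeros(len(kept), dtype=int)
    current = 0
    for j in range(1, len(kept)):
        t_prev, t_cur = kept.times[j - 1], kept.times[j]
        gap = orig_idx[j] - orig_idx[j - 1] > 1
        new_trial = events.trial[orig_idx[j]] != events.trial[orig_idx[j - 1]]
        crosses_turn = any(t_prev < t_a and t_cur > t_b for t_a, t_b in intervals)
        if gap or new_trial or crosses_turn:
            current += 1
        seg[j] = current
    return replace(kept, trial=seg)


def classify_foot_side(events: GaitEventSeries, sig: BodyFrameSignal) -> GaitEventSeries:
    """Label each event L or R from the mean roll rate around the event.

    The roll rate (rotation about the AP axis) tips toward alternate sides on
    alternate steps.  The raw feature is the mean of ``w_AP`` in a +/-150 ms
    window; its sign decides the side.  Because device roll polarity depends on
    strap placement, the sign->side mapping is chosen per recording as the one
    that makes labels alternate best within segments (ties keep positive->L).
    Events whose window has no roll energy are labeled ``unknown``.
    """
    if len(events) == 0:
        return events
    half = 0.150
    means = np.empty(len(events))
    for i, tc in enumerate(events.times):
        m = (sig.t >= tc - half) & (sig.t <= tc + half)
        means[i] = sig.w_AP[m].mean() if m.any() else 0.0
    energy_ok = np.abs(means) > 1e-9

    def labels_for(polarity: int) -> list[str]:
        out = []
        for ok, v in zip(energy_ok, means):
            if not ok:
                out.append("unknown")
            else:
                out.append("L" if polarity * v > 0 else "R")
        return out

    def alternation_score(labels: list[str]) -> int:
        score = 0
        for tr in np.unique(events.trial):
            lab = [l for l, t in zip(labels, events.trial) if t == tr and l != "unknown"]
            score += sum(1 for a, b in zip(lab, lab[1:]) if a != b)
        return score

    cand = {p: labels_for(p) for p in (+1, -1)}
    best = max((+1, -1), key=lambda p: (alternation_score(cand[p]), p))
    return events.with_feet(cand[best])


@dataclass(frozen=True)
class MatchResult:
    """One-to-one alignment of candidate events to reference events."""

    pairs: list[tuple[int, int]]
    unmatched_candidate: int
    unmatched_reference: int
    errors: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_matched(self) -> int:
        return len(self.pairs)

    @property
    def mean_error(self) -> float:
        return float(np.mean(self.errors)) if self.errors.size else float("nan")

    @property
    def sd_error(self) -> float:
        return float(np.std(self.errors, ddof=1)) if self.errors.size > 1 else 0.0


def match_events(
    candidate: GaitEventSeries, reference: GaitEventSeries, tol: float = 0.050
) -> MatchResult:
    """Greedy one-to-one nearest-neighbour matching within ``tol`` seconds.

    Candidate/reference pairs are accepted in order of increasing absolute
    time difference; no event on either side is matched twice.  Signed timing
    errors are candidate minus reference.
    """
    if tol <= 0:
        raise ParameterError("tol must be > 0")
    ct, rt = candidate.times, reference.times
    pairs_all = []
    for i, t in enumerate(ct):
        j0 = np.searchsorted(rt, t)
        for j in (j0 - 1, j0, j0 + 1):
            if 0 <= j < len(rt) and abs(t - rt[j]) <= tol:
                pairs_all.append((abs(t - rt[j]), i, j))
    pairs_all.sort()
    used_c: set[int] = set()
    used_r: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, i, j in pairs_all:
        if i in used_c or j in used_r:
            continue
        used_c.add(i)
        used_r.add(j)
        pairs.append((i, j))
    pairs.sort()
    errors = np.array([ct[i] - rt[j] for i, j in pairs])
    return MatchResult(
        pairs=pairs,
        unmatched_candidate=len(ct) - len(pairs),
        unmatched_reference=len(rt) - len(pairs),
        errors=errors,
    )
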