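"""Synthetic gait cohorts: ground truth, IMU traces, and reference devices.

The generator emulates the validation study's walking protocol so that every
pipeline stage can be tested against known truth: two groups (PD-like and
healthy-elderly-like, 12 subjects each by default) walk a 26-m path — two
13-m straight passes joined by a single 2-s turn — under three cueing
conditions (self-paced, 100% RAC, 110% RAC), while three devices record
simultaneously: the trunk IMU, heel footswitches (all heel strikes, small
timing jitter), and a 7-m pressure walkway capturing only the steps that land
on it (adding per-step lengths, small length jitter).

Step timing/length structure per subject x condition:

* step durations and lengths are i.i.d. draws from a truncated normal
  (+/- 4 SD) with the group profile's mean and CV, with a time-length
  correlation rho (default 0.3);
* PD-like profiles are slower, shorter-stepped and more variable than
  HE-like ones; rhythmic cueing entrains the mean (110% cueing divides the
  mean step time by 1.1) and shrinks the CV by a per-group reduction factor;
* feet alternate strictly, starting from a seeded random side.

The IMU trace is built in the body frame and mapped back to the device frame:
a vertical-acceleration biphasic pulse peaks exactly at each heel strike
(amplitude grows with step length); the anterior channel carries, per step, a
half-period sine calibrated analytically so its drift-corrected double
integral equals the true step length; the roll rate carries alternating-sign
bursts encoding foot side; the yaw rate shows a plateau during the turn.
Gaussian noise is added at a configurable SNR.  All randomness descends from
one master seed; regeneration is bit-exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .imu_io import STANDARD_GRAVITY, GaitEventSeries, ImuRecording

__all__ = [
    "GaitProfile",
    "TrialTruth",
    "SimulationTruth",
    "CohortConfig",
    "CohortDataset",
    "DEFAULT_PROFILES",
    "simulate_step_sequence",
    "simulate_trial",
    "synthesize_imu",
    "emulate_reference_devices",
    "generate_cohort",
    "truth_outcome_table",
    "walkway_step_capacity",
]

CONDITIONS = ("self", "100", "110")

#: Non-physiological CV guard (percent).
MAX_CV = 40.0


@dataclass(frozen=True)
class GaitProfile:
    """Group-level gait parameters and the cueing entrainment rule.

    ``mean_step_time``/``mean_step_length`` and their CVs (percent) describe
    self-paced walking.  Under cueing, the mean step time follows the cue
    tempo perfectly (100% leaves it unchanged, 110% divides it by 1.1), CVs
    shrink by ``cv_reduction``, and 110% cueing lengthens steps by
    ``length_boost_110`` (faster cadence with longer steps).
    """

    group: str
    mean_step_time: float = 0.55
    step_time_cv: float = 2.0
    mean_step_length: float = 0.65
    step_length_cv: float = 2.5
    cv_reduction: float = 0.9
    length_boost_110: float = 1.05

    def params_for(self, condition: str) -> tuple[float, float, float, float]:
        """(mean time, time CV, mean length, length CV) under a condition."""
        if condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        mt, cvt = self.mean_step_time, self.step_time_cv
        ml, cvl = self.mean_step_length, self.step_length_cv
        if condition in ("100", "110"):
            cvt *= self.cv_reduction
            cvl *= self.cv_reduction
        if condition == "110":
            mt /= 1.1
            ml *= self.length_boost_110
        return mt, cvt, ml, cvl


DEFAULT_PROFILES = {
    "HE": GaitProfile(group="HE", mean_step_time=0.55, step_time_cv=2.0,
                      mean_step_length=0.65, step_length_cv=2.5, cv_reduction=0.9),
    "PD": GaitProfile(group="PD", mean_step_time=0.60, step_time_cv=4.0,
                      mean_step_length=0.50, step_length_cv=5.0, cv_reduction=0.7),
}


@dataclass(frozen=True)
class TrialTruth:
    """Ground truth for one walking trial.

    ``event_times`` are true heel-strike times; ``lengths`` aligns to events
    (the length of the step *ending* at each event; NaN at each pass start);
    ``positions`` is the cumulative distance from the start of the event's
    pass; ``turn_window`` brackets the mid-trial turn (None for straight-only
    sequences).
    """

    event_times: np.ndarray
    feet: tuple[str, ...]
    lengths: np.ndarray
    pass_id: np.ndarray
    positions: np.ndarray
    turn_window: tuple[float, float] | None
    seed: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.event_times) <= 0):
            raise ValueError("event times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.event_times)

    @property
    def duration(self) -> float:
        return float(self.event_times[-1])

    def step_durations(self) -> np.ndarray:
        """Within-pass step durations (never across the turn)."""
        out = []
        for p in np.unique(self.pass_id):
            out.append(np.diff(self.event_times[self.pass_id == p]))
        return np.concatenate(out) if out else np.empty(0)

    def step_lengths(self) -> np.ndarray:
        """Within-pass step lengths, aligned with :meth:`step_durations`."""
        out = []
        for p in np.unique(self.pass_id):
            le = self.lengths[self.pass_id == p][1:]
            out.append(le)
        vals = np.concatenate(out) if out else np.empty(0)
        return vals[np.isfinite(vals)]


@dataclass(frozen=True)
class SimulationTruth:
    """Per subject x condition ground truth: the trial list plus provenance."""

    subject: str
    group: str
    condition: str
    trials: tuple[TrialTruth, ...]
    seed: int


def _draw_steps(
    rng: np.random.Generator,
    n_steps: int,
    mean_t: float,
    cv_t: float,
    mean_l: float,
    cv_l: float,
    rho: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Correlated truncated-normal (+/-4 SD) step durations and lengths."""
    cov = np.array([[1.0, rho], [rho, 1.0]])
    chol = np.linalg.cholesky(cov)
    z = np.empty((n_steps, 2))
    filled = 0
    while filled < n_steps:
        draw = (chol @ rng.standard_normal((2, n_steps - filled))).T
        ok = np.all(np.abs(draw) <= 4.0, axis=1)
        take = draw[ok]
        z[filled : filled + len(take)] = take
        filled += len(take)
    times = mean_t * (1.0 + z[:, 0] * cv_t / 100.0)
    lengths = mean_l * (1.0 + z[:, 1] * cv_l / 100.0)
    return np.maximum(times, 0.05), np.maximum(lengths, 0.01)


def _alternating_feet(n: int, rng: np.random.Generator) -> tuple[str, ...]:
    start = rng.integers(0, 2)
    return tuple("LR"[(start + i) % 2] for i in range(n))


def simulate_step_sequence(
    profile: GaitProfile,
    n_steps: int,
    seed: int,
    condition: str = "self",
    rho: float = 0.3,
    t_start: float = 1.0,
) -> TrialTruth:
    """One straight walking bout (no turn) of ``n_steps`` steps.

    Events are the cumulative sums of i.i.d. truncated-normal step durations;
    ``n_steps`` steps produce ``n_steps + 1`` heel strikes.  Deterministic for
    a fixed seed.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    mt, cvt, ml, cvl = profile.params_for(condition)
    for cv in (cvt, cvl):
        if cv >= MAX_CV:
            raise ValueError(f"CV {cv}% rejected as non-physiological (>= {MAX_CV}%)")
    rng = np.random.default_rng(seed)
    durations, lengths = _draw_steps(rng, n_steps, mt, cvt, ml, cvl, rho)
    times = t_start + np.concatenate([[0.0], np.cumsum(durations)])
    ev_lengths = np.concatenate([[np.nan], lengths])
    positions = np.concatenate([[0.0], np.cumsum(lengths)])
    return TrialTruth(
        event_times=times,
        feet=_alternating_feet(len(times), rng),
        lengths=ev_lengths,
        pass_id=np.zeros(len(times), dtype=int),
        positions=positions,
        turn_window=None,
        seed=seed,
    )


def simulate_trial(
    profile: GaitProfile,
    condition: str,
    seed: int,
    path_half_length: float = 13.0,
    turn_duration: float = 2.0,
    rho: float = 0.3,
) -> TrialTruth:
    """One full trial: two straight passes joined by a mid-trial turn.

    Each pass covers ``path_half_length`` meters (steps drawn until the
    cumulative distance reaches it); the turn contributes a yaw plateau and a
    gap with no heel strikes.
    """
    mt, cvt, ml, cvl = profile.params_for(condition)
    for cv in (cvt, cvl):
        if cv >= MAX_CV:
            raise ValueError(f"CV {cv}% rejected as non-physiological (>= {MAX_CV}%)")
    rng = np.random.default_rng(seed)

    def one_pass(t0: float):
        n_guess = int(np.ceil(path_half_length / ml)) + 8
        durations, lengths = _draw_steps(rng, n_guess, mt, cvt, ml, cvl, rho)
        pos = np.cumsum(lengths)
        # the walker stops before overstepping the straight path
        n = int(np.searchsorted(pos, path_half_length))
        n = max(2, min(n, n_guess))
        times = t0 + np.concatenate([[0.0], np.cumsum(durations[:n])])
        ev_len = np.concatenate([[np.nan], lengths[:n]])
        positions = np.concatenate([[0.0], pos[:n]])
        return times, ev_len, positions

    t1, l1, p1 = one_pass(t0=1.0)
    turn_start = t1[-1] + 0.3
    turn_end = turn_start + turn_duration
    t2, l2, p2 = one_pass(t0=turn_end + 0.3)

    times = np.concatenate([t1, t2])
    lengths = np.concatenate([l1, l2])
    positions = np.concatenate([p1, p2])
    pass_id = np.concatenate([np.zeros(len(t1), int), np.ones(len(t2), int)])
    feet = _alternating_feet(len(times), rng)
    return TrialTruth(
        event_times=times,
        feet=feet,
        lengths=lengths,
        pass_id=pass_id,
        positions=positions,
        turn_window=(turn_start, turn_end),
        seed=seed,
    )


# --- IMU synthesis ----------------------------------------------------------

_UD_SIGMA = 0.030  # s, main heel-strike pulse width
_UD_REBOUND_SIGMA = 0.050
_UD_REBOUND_DELAY = 0.120
_ROLL_SIGMA = 0.050
_ROLL_AMP = 1.0  # rad/s
_TURN_YAW = 1.2  # rad/s plateau


def _gaussian(t: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / sigma) ** 2)


def synthesize_imu(
    truth: TrialTruth,
    snr_db: float = 12.0,
    seed: int = 0,
    fs: float = 100.0,
    meta: dict | None = None,
) -> ImuRecording:
    """Render a trial's ground truth as a six-channel device-frame recording.

    Clean body-frame channels are constructed first (see module docstring),
    mapped to the device frame by the inverse of the anatomical relabeling,
    then Gaussian noise is added per channel at ``snr_db`` relative to that
    channel's clean variance (channels with no signal stay noise-free so a
    silent channel does not fabricate energy).
    """
    rng = np.random.default_rng(seed)
    t_end = truth.event_times[-1] + 1.0
    n = int(np.round(t_end * fs)) + 1
    t = np.arange(n) / fs

    a_UD = np.zeros(n)
    a_AP = np.zeros(n)
    w_AP = np.zeros(n)
    w_UD = np.zeros(n)

    ev = truth.event_times
    lengths = truth.lengths
    mean_len = np.nanmean(lengths) if np.isfinite(lengths).any() else 0.6

    for i, te in enumerate(ev):
        L = lengths[i] if np.isfinite(lengths[i]) else mean_len
        amp = 1.5 + 3.0 * L
        a_UD += amp * _gaussian(t, te, _UD_SIGMA)
        a_UD -= 0.4 * amp * _gaussian(t, te + _UD_REBOUND_DELAY, _UD_REBOUND_SIGMA)
        sign = 1.0 if truth.feet[i] == "L" else -1.0
        w_AP += sign * _ROLL_AMP * _gaussian(t, te, _ROLL_SIGMA)

    # anterior channel: per-step sine whose drift-corrected double integral
    # equals the true step length (c = 2*pi*L / T^2, one full period per step)
    for p in np.unique(truth.pass_id):
        m = truth.pass_id == p
        pe = ev[m]
        pl = lengths[m]
        for i in range(1, len(pe)):
            t_i, t_j = pe[i - 1], pe[i]
            T = t_j - t_i
            L = pl[i] if np.isfinite(pl[i]) else mean_len
            c = 2.0 * np.pi * L / T**2
            seg = (t >= t_i) & (t < t_j)
            a_AP[seg] += c * np.sin(2.0 * np.pi * (t[seg] - t_i) / T)

    if truth.turn_window is not None:
        ts, te_ = truth.turn_window
        ramp = 0.2
        w_UD += _TURN_YAW * np.clip(
            np.minimum((t - ts) / ramp, (te_ - t) / ramp), 0.0, 1.0
        )

    a_UD += STANDARD_GRAVITY  # gravity-included vertical channel

    def noisy(x: np.ndarray) -> np.ndarray:
        power = float(np.var(x))
        if power <= 0:
            return x
        sd = np.sqrt(power / 10.0 ** (snr_db / 10.0))
        return x + rng.normal(0.0, sd, size=len(x))

    a_UD, a_AP = noisy(a_UD), noisy(a_AP)
    w_AP, w_UD = noisy(w_AP), noisy(w_UD)
    a_LR = np.zeros(n)
    w_LR = np.zeros(n)

    # invert the anatomical relabeling back to the device frame
    return ImuRecording(
        t=t,
        a_x=a_LR,
        a_y=-a_UD,
        a_z=-a_AP,
        w_x=w_LR,
        w_y=-w_UD,
        w_z=-w_AP,
        fs=fs,
        meta=dict(meta or {}),
    )


# --- reference devices ------------------------------------------------------

def walkway_step_capacity(window_m: float = 7.0, step_m: float = 0.6) -> int:
    """Maximum number of complete steps a walkway window can capture per pass."""
    if window_m <= 0 or step_m <= 0:
        raise ValueError("window and step length must be > 0")
    return int(np.floor(window_m / step_m))


def emulate_reference_devices(
    truth: TrialTruth,
    walkway_window: float = 7.0,
    timing_jitter: float = 0.005,
    length_jitter: float = 0.01,
    seed: int = 0,
    path_half_length: float = 13.0,
    trial_index: int = 0,
) -> tuple[GaitEventSeries, GaitEventSeries]:
    """Footswitch and walkway event series for one trial.

    The footswitch captures every true heel strike (Gaussian timing jitter,
    default SD 5 ms).  The walkway captures only events whose cumulative
    position falls inside a centrally placed window of ``walkway_window``
    meters on each pass, and adds true step lengths with Gaussian jitter
    (default SD 1 cm); the first event on the mat has no preceding footprint,
    so its length is unknown.
    """
    if walkway_window > path_half_length:
        raise ValueError("walkway window cannot exceed the straight path length")
    rng = np.random.default_rng(seed)

    fs_times = truth.event_times + rng.normal(0.0, timing_jitter, len(truth))
    fs_times = np.sort(fs_times)
    footswitch = GaitEventSeries(
        times=fs_times,
        feet=truth.feet,
        device="footswitch",
        trial=truth.pass_id + 2 * trial_index,
    )

    lo = (path_half_length - walkway_window) / 2.0
    hi = lo + walkway_window
    on_mat = (truth.positions >= lo) & (truth.positions <= hi)
    ww_times = truth.event_times[on_mat] + rng.normal(0.0, timing_jitter, int(on_mat.sum()))
    order = np.argsort(ww_times)
    ww_lengths = truth.lengths[on_mat] + rng.normal(0.0, length_jitter, int(on_mat.sum()))
    ww_pass = truth.pass_id[on_mat]
    # first footprint of each pass on the mat has no measurable step length
    for p in np.unique(ww_pass):
        first = np.flatnonzero(ww_pass == p)[0]
        ww_lengths[first] = np.nan
    walkway = GaitEventSeries(
        times=ww_times[order],
        feet=tuple(np.array(truth.feet)[on_mat][order]),
        device="walkway",
        trial=(ww_pass + 2 * trial_index)[order],
        lengths=ww_lengths[order],
    )
    return footswitch, walkway


# --- cohort generation ------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Study-scale simulation settings (defaults emulate the protocol)."""

    n_per_group: dict = field(default_factory=lambda: {"PD": 12, "HE": 12})
    profiles: dict = field(default_factory=lambda: dict(DEFAULT_PROFILES))
    conditions: tuple[str, ...] = CONDITIONS
    min_walkway_events: int = 40
    max_trials: int = 8
    snr_db: float = 12.0
    walkway_window: float = 7.0
    path_half_length: float = 13.0
    timing_jitter: float = 0.005
    length_jitter: float = 0.01
    fs: float = 100.0
    rho: float = 0.3


@dataclass(frozen=True)
class SubjectConditionData:
    """All artifacts for one subject under one cueing condition."""

    subject: str
    group: str
    condition: str
    truth: SimulationTruth
    recordings: tuple[ImuRecording, ...]
    footswitch: tuple[GaitEventSeries, ...]
    walkway: tuple[GaitEventSeries, ...]


@dataclass(frozen=True)
class CohortDataset:
    """A full simulated cohort plus its generation manifest."""

    config: CohortConfig
    master_seed: int
    cells: tuple[SubjectConditionData, ...]

    def cell(self, subject: str, condition: str) -> SubjectConditionData:
        for c in self.cells:
            if c.subject == subject and c.condition == condition:
                return c
        raise KeyError((subject, condition))

    @property
    def subjects(self) -> list[tuple[str, str]]:
        seen = {}
        for c in self.cells:
            seen.setdefault(c.subject, c.group)
        return list(seen.items())


def generate_cohort(config: CohortConfig | None = None, seed: int = 0) -> CohortDataset:
    """Simulate the full study: subjects x conditions x trials, all devices.

    Trials are repeated (up to ``max_trials``) until at least
    ``min_walkway_events`` heel strikes land on the walkway for the condition,
    mirroring the protocol's minimum-step requirement.  Every random draw
    descends from ``seed`` through a spawned seed tree, so regeneration is
    bit-exact.
    """
    config = config or CohortConfig()
    root = np.random.SeedSequence(seed)
    cells: list[SubjectConditionData] = []
    for group in sorted(config.n_per_group):
        profile = config.profiles[group]
        for si in range(config.n_per_group[group]):
            subject = f"{group}{si + 1:02d}"
            for condition in config.conditions:
                cell_seed = _spawn_seed(root, group, si, condition)
                cells.append(
                    _generate_cell(subject, group, condition, profile, config, cell_seed)
                )
    return CohortDataset(config=config, master_seed=seed, cells=tuple(cells))


def _spawn_seed(root: np.random.SeedSequence, group: str, si: int, condition: str) -> int:
    # stable across processes: no reliance on Python's randomized str hash
    group_code = int.from_bytes(group.encode()[:4].ljust(4, b"\0"), "big") % (2**16)
    key = (group_code, si, CONDITIONS.index(condition))
    child = np.random.SeedSequence(entropy=root.entropy, spawn_key=key)
    return int(child.generate_state(1)[0] % (2**31))


def _generate_cell(
    subject: str,
    group: str,
    condition: str,
    profile: GaitProfile,
    config: CohortConfig,
    cell_seed: int,
) -> SubjectConditionData:
    rng = np.random.default_rng(cell_seed)
    trials: list[TrialTruth] = []
    recordings: list[ImuRecording] = []
    fsw: list[GaitEventSeries] = []
    ww: list[GaitEventSeries] = []
    total_ww = 0
    while total_ww < config.min_walkway_events and len(trials) < config.max_trials:
        tseed = int(rng.integers(0, 2**31))
        truth = simulate_trial(
            profile, condition, seed=tseed,
            path_half_length=config.path_half_length, rho=config.rho,
        )
        meta = {"subject": subject, "group": group, "condition": condition,
                "trial": str(len(trials))}
        rec = synthesize_imu(
            truth, snr_db=config.snr_db, seed=int(rng.integers(0, 2**31)),
            fs=config.fs, meta=meta,
        )
        f, w = emulate_reference_devices(
            truth,
            walkway_window=config.walkway_window,
            timing_jitter=config.timing_jitter,
            length_jitter=config.length_jitter,
            seed=int(rng.integers(0, 2**31)),
            path_half_length=config.path_half_length,
            trial_index=len(trials),
        )
        trials.append(truth)
        recordings.append(rec)
        fsw.append(f)
        ww.append(w)
        total_ww += len(w)
    sim = SimulationTruth(
        subject=subject, group=group, condition=condition,
        trials=tuple(trials), seed=cell_seed,
    )
    return SubjectConditionData(
        subject=subject, group=group, condition=condition,
        truth=sim, recordings=tuple(recordings),
        footswitch=tuple(fsw), walkway=tuple(ww),
    )


def truth_outcome_table(dataset: CohortDataset, max_events: int = 50):
    """Expected (noise-free) outcome table computed from ground truth.

    One row per subject x condition x device x measure.  The ``smartmove``
    rows use the true heel-strike times and true step lengths; ``reference``
    rows use the emulated footswitch times (step-time measures) and walkway
    lengths (step-length measures), so residual device differences reflect
    only the configured jitter and the walkway's spatial window.
    """
    import pandas as pd

    from .spatiotemporal import build_delta_series, outcome_measures, step_time_intervals

    rows = []
    for cell in dataset.cells:
        base = {"subject": cell.subject, "group": cell.group, "condition": cell.condition}
        # true step times / lengths pooled across trials
        true_time_lists = [tr.step_durations() for tr in cell.truth.trials]
        true_len_lists = [tr.step_lengths() for tr in cell.truth.trials]
        fs_time_lists = []
        for series in cell.footswitch:
            fs_time_lists.extend(step_time_intervals(series))
        ww_len_lists = []
        for series in cell.walkway:
            le = series.lengths
            if le is not None:
                for tr in np.unique(series.trial):
                    vals = le[series.trial == tr]
                    vals = vals[np.isfinite(vals)]
                    if vals.size:
                        ww_len_lists.append(vals)
        for device, kind, lists in (
            ("smartmove", "time", true_time_lists),
            ("smartmove", "length", true_len_lists),
            ("reference", "time", fs_time_lists),
            ("reference", "length", ww_len_lists),
        ):
            series = build_delta_series(lists, kind=kind, max_events=max_events)
            if len(series) < 2:
                continue
            om = outcome_measures(series)
            prefix = "step_time" if kind == "time" else "step_length"
            rows.append({**base, "device": device, "measure": f"{prefix}_delta_M",
                         "value": om.delta_M})
            rows.append({**base, "device": device, "measure": f"{prefix}_delta_CV",
                         "value": om.delta_CV})
    return pd.DataFrame(rows)
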