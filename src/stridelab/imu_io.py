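"""Reading, validation, and anatomical re-orientation of raw IMU recordings.

A trunk-worn smartphone records six inertial channels at a nominal 100 Hz:
tri-axial acceleration (gravity included) and tri-axial rotation rate, both in
the device's own x/y/z frame.  With the device strapped at the navel, screen
toward the subject and audio jack up, the device frame maps onto the anatomical
anterior-posterior (AP), up-down (UD) and left-right (LR) axes by a pure
sign/relabel transform::

    a_AP = -a_z   a_UD = -a_y   a_LR = a_x
    w_AP = -w_z   w_UD = -w_y   w_LR = w_x

so positive values mean anterior, upward and leftward acceleration, and w_AP,
w_UD, w_LR are roll, yaw and pitch rates respectively.

File formats are deliberately plain: comma-separated values with '#'-prefixed
``key=value`` metadata lines, SI units internally (m/s^2, rad/s, seconds from
trial start).
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "STANDARD_GRAVITY",
    "ImuRecording",
    "BodyFrameSignal",
    "GaitEventSeries",
    "FormatError",
    "DataError",
    "RateError",
    "read_imu_csv",
    "write_imu_csv",
    "to_body_frame",
    "read_events_csv",
    "write_events_csv",
]

#: Conventional standard gravity used for the g -> m/s^2 conversion.
STANDARD_GRAVITY = 9.80665

IMU_COLUMNS = ("t", "ax", "ay", "az", "gx", "gy", "gz")
EVENT_COLUMNS = ("time_s", "foot", "device", "step_length_m", "trial")

FOOT_LABELS = frozenset({"L", "R", "unknown"})
DEVICE_LABELS = frozenset({"smartmove", "footswitch", "walkway"})

#: Fractional tolerance on the median sampling interval vs. the nominal rate.
RATE_TOLERANCE = 0.05


class FormatError(ValueError):
    """Malformed file: missing/duplicate columns or unparseable values."""


class DataError(ValueError):
    """Structurally valid file with invalid data (non-monotone time, NaNs)."""


class RateError(DataError):
    """Observed sampling rate deviates too far from the nominal rate."""


@dataclass(frozen=True)
class ImuRecording:
    """A validated six-channel inertial recording in the device frame.

    Accelerations are in m/s^2 (gravity included), rotation rates in rad/s,
    timestamps in seconds from trial start, uniformly sampled.
    """

    t: np.ndarray
    a_x: np.ndarray
    a_y: np.ndarray
    a_z: np.ndarray
    w_x: np.ndarray
    w_y: np.ndarray
    w_z: np.ndarray
    fs: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.t)
        channels = (self.a_x, self.a_y, self.a_z, self.w_x, self.w_y, self.w_z)
        if n < 2:
            raise DataError("recording must contain at least 2 samples")
        if any(len(c) != n for c in channels):
            raise DataError("all channels must have equal length")
        if not all(np.isfinite(c).all() for c in (self.t, *channels)):
            raise DataError("non-finite samples in recording")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise DataError("time stamps must be strictly increasing")
        observed = 1.0 / float(np.median(dt))
        if abs(observed - self.fs) > RATE_TOLERANCE * self.fs:
            raise RateError(
                f"observed sampling rate {observed:.2f} Hz deviates more than "
                f"{RATE_TOLERANCE:.0%} from nominal {self.fs:.2f} Hz"
            )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass(frozen=True)
class BodyFrameSignal:
    """IMU channels relabeled into anatomical AP/UD/LR axes (same time base)."""

    t: np.ndarray
    a_AP: np.ndarray
    a_UD: np.ndarray
    a_LR: np.ndarray
    w_AP: np.ndarray
    w_UD: np.ndarray
    w_LR: np.ndarray
    fs: float
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass(frozen=True)
class GaitEventSeries:
    """Heel-strike (analogue) event times with foot labels and provenance.

    ``lengths`` holds per-step displacements aligned to the intervals between
    successive within-trial events; NaN marks an unknown length.  ``trial``
    carries the trial/segment index of each event so that downstream interval
    construction never spans a trial boundary.
    """

    times: np.ndarray
    feet: tuple[str, ...]
    device: str
    trial: np.ndarray
    lengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        trial = np.asarray(self.trial, dtype=int)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "trial", trial)
        object.__setattr__(self, "feet", tuple(self.feet))
        if self.lengths is not None:
            object.__setattr__(self, "lengths", np.asarray(self.lengths, dtype=float))
        if not (len(times) == len(self.feet) == len(trial)):
            raise DataError("times, feet and trial must have equal length")
        if self.device not in DEVICE_LABELS:
            raise DataError(f"unknown device label {self.device!r}")
        for f in self.feet:
            if f not in FOOT_LABELS:
                raise DataError(f"unknown foot label {f!r}")
        for tr in np.unique(trial):
            tt = times[trial == tr]
            if np.any(np.diff(tt) <= 0):
                raise DataError(f"event times not strictly increasing in trial {tr}")
        if self.lengths is not None and len(self.lengths) != len(times):
            raise DataError("lengths must align with events (NaN where unknown)")

    def __len__(self) -> int:
        return len(self.times)

    def with_feet(self, feet) -> "GaitEventSeries":
        return replace(self, feet=tuple(feet))

    def subset(self, mask) -> "GaitEventSeries":
        mask = np.asarray(mask, dtype=bool)
        return GaitEventSeries(
            times=self.times[mask],
            feet=tuple(f for f, m in zip(self.feet, mask) if m),
            device=self.device,
            trial=self.trial[mask],
            lengths=None if self.lengths is None else self.lengths[mask],
        )

    def trials(self) -> list[np.ndarray]:
        """Event times grouped by trial index, in trial order."""
        return [self.times[self.trial == tr] for tr in np.unique(self.trial)]


def _parse_meta(lines: list[str]) -> dict:
    meta: dict = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if "=" in body:
            key, _, value = body.partition("=")
            meta[key.strip()] = value.strip()
    return meta


def read_imu_csv(path, units: str = "ms2", nominal_fs: float | None = None) -> ImuRecording:
    """Read a six-channel IMU CSV into a validated :class:`ImuRecording`.

    Parameters
    ----------
    path : path-like
        CSV with header columns ``t,ax,ay,az,gx,gy,gz`` (gyroscope in rad/s)
        and optional ``# key=value`` metadata lines.
    units : {"ms2", "g"}
        Unit of the stored accelerations.  ``"g"`` multiplies by 9.80665.
    nominal_fs : float, optional
        Nominal sampling rate in Hz.  Defaults to a ``fs`` metadata entry, or
        100 Hz when absent.
    """
    if units not in ("ms2", "g"):
        raise ValueError(f"units must be 'ms2' or 'g', got {units!r}")
    with open(path, "r", newline="") as fh:
        text = fh.read()
    meta_lines = [ln for ln in text.splitlines() if ln.startswith("#")]
    body = "\n".join(ln for ln in text.splitlines() if not ln.startswith("#") and ln.strip())
    meta = _parse_meta(meta_lines)

    reader = csv.reader(io.StringIO(body))
    try:
        header = [h.strip() for h in next(reader)]
    except StopIteration:
        raise FormatError(f"{path}: empty file") from None
    if len(set(header)) != len(header):
        raise FormatError(f"{path}: duplicate columns in header")
    missing = [c for c in IMU_COLUMNS if c not in header]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    idx = {c: header.index(c) for c in IMU_COLUMNS}

    rows = list(reader)
    try:
        data = {c: np.array([float(r[idx[c]]) for r in rows]) for c in IMU_COLUMNS}
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}: unparseable numeric value ({exc})") from None

    scale = STANDARD_GRAVITY if units == "g" else 1.0
    if nominal_fs is None:
        nominal_fs = float(meta.get("fs", 100.0))
    return ImuRecording(
        t=data["t"],
        a_x=data["ax"] * scale,
        a_y=data["ay"] * scale,
        a_z=data["az"] * scale,
        w_x=data["gx"],
        w_y=data["gy"],
        w_z=data["gz"],
        fs=nominal_fs,
        meta=meta,
    )


def write_imu_csv(rec: ImuRecording, path) -> None:
    """Write a recording in the dialect :func:`read_imu_csv` accepts.

    Values are serialized with 9+ significant digits so a read/write/read
    round-trip is the identity to text precision.
    """
    with open(path, "w", newline="") as fh:
        for key, value in {**rec.meta, "fs": f"{rec.fs:g}"}.items():
            fh.write(f"# {key}={value}\n")
        writer = csv.writer(fh)
        writer.writerow(IMU_COLUMNS)
        cols = (rec.t, rec.a_x, rec.a_y, rec.a_z, rec.w_x, rec.w_y, rec.w_z)
        for row in zip(*cols):
            writer.writerow([f"{v:.12g}" for v in row])


def to_body_frame(rec: ImuRecording) -> BodyFrameSignal:
    """Relabel device-frame channels into anatomical AP/UD/LR axes.

    The transform is a pure sign/permutation map (norm-preserving sample-wise):
    a_AP = -a_z, a_UD = -a_y, a_LR = a_x and likewise for rotation rates.
    """
    return BodyFrameSignal(
        t=rec.t.copy(),
        a_AP=-rec.a_z,
        a_UD=-rec.a_y,
        a_LR=rec.a_x.copy(),
        w_AP=-rec.w_z,
        w_UD=-rec.w_y,
        w_LR=rec.w_x.copy(),
        fs=rec.fs,
        meta=dict(rec.meta),
    )


def write_events_csv(events: GaitEventSeries, path) -> None:
    """Write one row per event: time_s, foot, device, step_length_m, trial.

    Unknown step lengths serialize as empty cells and round-trip as NaN.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(EVENT_COLUMNS)
        lengths = events.lengths
        for i in range(len(events)):
            length = ""
            if lengths is not None and math.isfinite(lengths[i]):
                length = f"{lengths[i]:.12g}"
            writer.writerow(
                [f"{events.times[i]:.12g}", events.feet[i], events.device, length,
                 int(events.trial[i])]
            )


def read_events_csv(path) -> GaitEventSeries:
    """Read an event CSV written by :func:`write_events_csv`."""
    with open(path, "r", newline="") as fh:
        reader = csv.reader(fh)
        header = [h.strip() for h in next(reader)]
        missing = [c for c in EVENT_COLUMNS[:4] if c not in header]
        if missing:
            raise FormatError(f"{path}: missing required columns {missing}")
        idx = {c: header.index(c) for c in header}
        times, feet, devices, lengths, trials = [], [], [], [], []
        for r in reader:
            if not r:
                continue
            times.append(float(r[idx["time_s"]]))
            feet.append(r[idx["foot"]])
            devices.append(r[idx["device"]])
            raw = r[idx["step_length_m"]].strip()
            lengths.append(float(raw) if raw else math.nan)
            trials.append(int(r[idx["trial"]]) if "trial" in idx and r[idx["trial"]] else 0)
    if times and len(set(devices)) > 1:
        raise DataError(f"{path}: mixed device labels in one series")
    device = devices[0] if devices else "smartmove"
    lengths_arr = np.array(lengths) if lengths else np.empty(0)
    if lengths_arr.size and np.all(np.isnan(lengths_arr)):
        lengths_arr = None
    elif not lengths_arr.size:
        lengths_arr = None
    return GaitEventSeries(
        times=np.array(times),
        feet=tuple(feet),
        device=device,
        trial=np.array(trials, dtype=int),
        lengths=lengths_arr,
    )
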