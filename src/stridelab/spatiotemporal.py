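"""Step-time and step-length delta-series and their outcome measures.

The delta-series of a subject x condition x device cell is the pooled sequence
of inter-step quantities (successive step times in seconds, or step lengths in
meters), concatenated across that subject's trials in trial order with no
interval spanning a trial boundary, then truncated to a maximum event count
(default 50).  Two outcome measures summarize each series:

* ``delta_M``  — the arithmetic mean (first-moment gait measure);
* ``delta_CV`` — the coefficient of variation, 100 * delta_SD / delta_M in
  percent, where delta_SD is the sample standard deviation (n-1 denominator)
  — the second-moment gait-variability measure.

Step lengths from the trunk IMU are estimated in two stages: a raw
anterior-posterior displacement per step by drift-corrected double
integration, then a ridge-regression calibration of per-step features against
reference (walkway) step lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import Ridge
from sklearn.model_selection import LeaveOneGroupOut

from .imu_io import BodyFrameSignal, GaitEventSeries

__all__ = [
    "DeltaSeries",
    "OutcomeMeasures",
    "StepLengthModel",
    "InsufficientDataError",
    "step_time_intervals",
    "step_length_intervals",
    "raw_step_displacement",
    "step_features",
    "fit_step_length_model",
    "build_delta_series",
    "outcome_measures",
]

MAX_EVENT_COUNT = 50

#: Physiological clip range for predicted step lengths, meters.
LENGTH_CLIP = (0.05, 2.5)

FEATURE_NAMES = ("raw_displacement", "step_time", "rms_a_AP", "rms_a_UD", "p2p_a_UD")


class InsufficientDataError(ValueError):
    """Too few events/values for the requested quantity."""


@dataclass(frozen=True)
class DeltaSeries:
    """Pooled inter-step quantities for one subject x condition x device."""

    values: np.ndarray
    kind: str  # {"time", "length"}
    trial_boundaries: tuple[int, ...]
    subject: str = ""
    group: str = ""
    condition: str = ""
    device: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.kind not in ("time", "length"):
            raise ValueError(f"kind must be 'time' or 'length', got {self.kind!r}")
        if np.any(self.values <= 0):
            raise ValueError("delta-series values must be strictly positive")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class OutcomeMeasures:
    """First- and second-moment summary of a delta-series."""

    delta_M: float
    delta_SD: float
    delta_CV: float
    n: int


def step_time_intervals(events: GaitEventSeries) -> list[np.ndarray]:
    """Successive event-time differences, one array per trial/segment.

    Trials with fewer than two events contribute nothing; no interval is ever
    computed across a trial boundary.
    """
    out = []
    for times in events.trials():
        if len(times) >= 2:
            out.append(np.diff(times))
    return out


def step_length_intervals(events: GaitEventSeries) -> list[np.ndarray]:
    """Per-trial step lengths aligned to the intervals between events.

    Uses the ``lengths`` attribute: the length stored on the *second* event of
    each within-trial pair (the displacement covered by that step).  Pairs with
    an unknown (NaN) length are dropped.
    """
    if events.lengths is None:
        return []
    out = []
    for tr in np.unique(events.trial):
        m = events.trial == tr
        lengths = events.lengths[m][1:]  # first event of a trial starts the first step
        lengths = lengths[np.isfinite(lengths)]
        if lengths.size:
            out.append(lengths)
    return out


def raw_step_displacement(
    sig: BodyFrameSignal, t_i: float, t_j: float, drift_correction: bool = True
) -> float:
    """Anterior displacement over one step by trapezoidal double integration.

    Integrates ``a_AP`` from ``t_i`` to ``t_j`` (successive heel-strike
    analogues) to velocity, applies a per-step drift correction, and integrates
    again to displacement.  The drift correction assumes the trunk's forward
    velocity fluctuation returns to its segment-start value at ``t_j`` (steady
    gait), i.e. the net acceleration over the step is zero: the linear velocity
    trend implied by v(t_j) - v(t_i) is subtracted before the second
    integration.
    """
    if not t_i < t_j:
        raise ValueError("t_i must precede t_j")
    m = (sig.t >= t_i) & (sig.t <= t_j)
    t = sig.t[m]
    a = sig.a_AP[m]
    if len(t) < 3:
        raise InsufficientDataError("step segment shorter than 3 samples")
    from scipy.integrate import cumulative_trapezoid

    v = cumulative_trapezoid(a, t, initial=0.0)
    if drift_correction:
        duration = t[-1] - t[0]
        v = v - (t - t[0]) / duration * v[-1]
    disp = np.trapezoid(v, t)
    return float(disp)


def step_features(sig: BodyFrameSignal, t_i: float, t_j: float) -> np.ndarray:
    """Per-step feature vector for the step-length calibration model.

    Features: drift-corrected raw AP displacement, step duration, RMS of a_AP,
    RMS of a_UD, and peak-to-peak a_UD over the step segment.
    """
    m = (sig.t >= t_i) & (sig.t <= t_j)
    a_ap = sig.a_AP[m]
    a_ud = sig.a_UD[m]
    disp = raw_step_displacement(sig, t_i, t_j)
    return np.array(
        [
            disp,
            t_j - t_i,
            float(np.sqrt(np.mean(a_ap**2))),
            float(np.sqrt(np.mean(a_ud**2))),
            float(np.ptp(a_ud)),
        ]
    )


@dataclass(frozen=True)
class StepLengthModel:
    """Ridge calibration from per-step IMU features to reference step length.

    Deterministic given training data and ``reg_weight``; features are
    standardized internally and coefficients are reported on the original
    feature scale.  Predictions are clipped to a physiological range.
    """

    coef: np.ndarray
    intercept: float
    reg_weight: float
    feature_means: np.ndarray
    feature_scales: np.ndarray
    train_rmse: float
    frac_within_10pct: float
    cv_rmse: float | None = None

    def predict(self, features: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(features, dtype=float))
        raw = X @ self.coef + self.intercept
        return np.clip(raw, *LENGTH_CLIP)


def fit_step_length_model(
    features: np.ndarray,
    reference_lengths: np.ndarray,
    reg_weight: float = 1e-3,
    subjects: np.ndarray | None = None,
) -> StepLengthModel:
    """Fit the ridge step-length calibration on walkway-matched steps.

    Parameters
    ----------
    features : (n_steps, n_features) array
        Per-step features from :func:`step_features`.
    reference_lengths : (n_steps,) array
        Matched reference (walkway) step lengths, meters.
    reg_weight : float
        Ridge penalty on standardized features.  ``0`` falls back to ordinary
        least squares and raises on rank-deficient features.
    subjects : array of labels, optional
        When given, a leave-one-subject-out cross-validated RMSE is computed
        so model quality is judged on held-out subjects.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(reference_lengths, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("features must be 2-D and aligned with reference lengths")
    if len(y) < 20:
        raise InsufficientDataError(
            f"need >= 20 training steps with reference lengths, got {len(y)}"
        )
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Z = (X - mu) / sd_safe

    if reg_weight < 0:
        raise ValueError("reg_weight must be >= 0")
    if reg_weight == 0:
        if np.linalg.matrix_rank(np.column_stack([Z, np.ones(len(Z))])) < Z.shape[1] + 1:
            raise np.linalg.LinAlgError(
                "rank-deficient features with reg_weight=0; use a positive reg_weight"
            )
        beta, *_ = np.linalg.lstsq(np.column_stack([Z, np.ones(len(Z))]), y, rcond=None)
        coef_z, intercept_z = beta[:-1], beta[-1]
    else:
        model = Ridge(alpha=reg_weight, fit_intercept=True)
        model.fit(Z, y)
        coef_z, intercept_z = model.coef_, float(model.intercept_)

    coef = coef_z / sd_safe
    intercept = float(intercept_z - coef @ mu)

    pred = np.clip(X @ coef + intercept, *LENGTH_CLIP)
    resid = pred - y
    train_rmse = float(np.sqrt(np.mean(resid**2)))
    frac10 = float(np.mean(np.abs(resid) <= 0.1 * y))

    cv_rmse = None
    if subjects is not None:
        subjects = np.asarray(subjects)
        if len(np.unique(subjects)) >= 2:
            errs = []
            for train, test in LeaveOneGroupOut().split(X, y, groups=subjects):
                sub = fit_step_length_model(X[train], y[train], reg_weight=reg_weight)
                errs.append((sub.predict(X[test]) - y[test]) ** 2)
            cv_rmse = float(np.sqrt(np.mean(np.concatenate(errs))))

    return StepLengthModel(
        coef=coef,
        intercept=intercept,
        reg_weight=reg_weight,
        feature_means=mu,
        feature_scales=sd_safe,
        train_rmse=train_rmse,
        frac_within_10pct=frac10,
        cv_rmse=cv_rmse,
    )


def build_delta_series(
    interval_lists: list[np.ndarray],
    kind: str,
    max_events: int = MAX_EVENT_COUNT,
    **labels,
) -> DeltaSeries:
    """Pool per-trial intervals in trial order and cap at ``max_events``.

    The cap (default 50 values per condition) keeps event counts comparable
    across subjects; truncation keeps the first values in collection order.
    """
    if max_events < 1:
        raise ValueError("max_events must be >= 1")
    boundaries: list[int] = []
    pooled: list[float] = []
    for intervals in interval_lists:
        if len(pooled) >= max_events:
            break
        boundaries.append(len(pooled))
        room = max_events - len(pooled)
        pooled.extend(np.asarray(intervals, dtype=float)[:room])
    return DeltaSeries(
        values=np.array(pooled),
        kind=kind,
        trial_boundaries=tuple(boundaries),
        **labels,
    )


def outcome_measures(series: DeltaSeries) -> OutcomeMeasures:
    """delta_M, delta_SD (n-1 denominator) and delta_CV = 100*SD/M."""
    v = series.values
    if len(v) < 2:
        raise InsufficientDataError("need at least 2 delta values for outcome measures")
    m = float(np.mean(v))
    sd = float(np.std(v, ddof=1))
    return OutcomeMeasures(delta_M=m, delta_SD=sd, delta_CV=100.0 * sd / m, n=len(v))
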