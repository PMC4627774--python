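"""End-to-end analysis: recordings -> events -> delta-series -> outcome table.

The device-comparison workflow enforces the protocol's equal-event-count rule:
step-time series are built only from IMU events that matched a footswitch
event (and vice versa), and step-length series only from steps bracketed by
matched walkway events, so the two devices always summarize the same steps.
Step lengths from the IMU are the ridge-calibrated predictions of
:mod:`stridelab.spatiotemporal`, trained on walkway-matched steps across the
cohort and evaluated on held-out subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import (
    DetectionParams,
    classify_foot_side,
    detect_heel_strike_analogues,
    exclude_turn_segments,
    match_events,
    preprocess,
)
from .imu_io import BodyFrameSignal, GaitEventSeries, ImuRecording, to_body_frame
from .spatiotemporal import (
    MAX_EVENT_COUNT,
    StepLengthModel,
    build_delta_series,
    fit_step_length_model,
    outcome_measures,
    step_features,
    step_time_intervals,
)

__all__ = [
    "TrialAnalysis",
    "analyze_recording",
    "collect_length_training",
    "cohort_outcomes",
]


@dataclass(frozen=True)
class TrialAnalysis:
    """Detected events and the preprocessed signal for one recording."""

    signal: BodyFrameSignal
    events: GaitEventSeries


def analyze_recording(
    rec: ImuRecording, params: DetectionParams = DetectionParams()
) -> TrialAnalysis:
    """Preprocess, detect heel-strike analogues, drop turns, label feet."""
    body = to_body_frame(rec)
    filtered = preprocess(body, params)
    events = detect_heel_strike_analogues(filtered, params)
    # turn detection and roll-sign classification use the unfiltered signal:
    # the band-pass removes the near-DC yaw plateau of a slow turn
    events = exclude_turn_segments(events, body, params)
    events = classify_foot_side(events, body)
    return TrialAnalysis(signal=filtered, events=events)


def _matched_step_pairs(
    imu_events: GaitEventSeries, reference: GaitEventSeries, tol: float
) -> list[tuple[float, float, float]]:
    """(t_i, t_j, reference_length) for consecutive matched reference steps.

    A usable step is a pair of reference events that are consecutive within a
    reference trial, both matched to IMU events, with a known reference
    length on the second event.
    """
    res = match_events(imu_events, reference, tol=tol)
    ref_to_imu = {j: i for i, j in res.pairs}
    out = []
    if reference.lengths is None:
        return out
    for tr in np.unique(reference.trial):
        idx = np.flatnonzero(reference.trial == tr)
        for a, b in zip(idx, idx[1:]):
            if a in ref_to_imu and b in ref_to_imu and np.isfinite(reference.lengths[b]):
                i, j = ref_to_imu[a], ref_to_imu[b]
                t_i, t_j = imu_events.times[i], imu_events.times[j]
                if t_j > t_i:
                    out.append((t_i, t_j, float(reference.lengths[b])))
    return out


def collect_length_training(
    analyses: list[TrialAnalysis],
    walkway_series: list[GaitEventSeries],
    subjects: list[str],
    tol: float = 0.050,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pool per-step features and walkway reference lengths across trials.

    Returns (features, reference_lengths, subject_labels) over every
    walkway-matched step, ready for :func:`fit_step_length_model`.
    """
    feats, refs, labels = [], [], []
    for analysis, walkway, subject in zip(analyses, walkway_series, subjects):
        for t_i, t_j, L in _matched_step_pairs(analysis.events, walkway, tol):
            try:
                feats.append(step_features(analysis.signal, t_i, t_j))
            except ValueError:
                continue
            refs.append(L)
            labels.append(subject)
    if not feats:
        return np.empty((0, 5)), np.empty(0), np.empty(0, dtype=object)
    return np.array(feats), np.array(refs), np.array(labels, dtype=object)


def _matched_time_intervals(
    imu_events: GaitEventSeries, footswitch: GaitEventSeries, tol: float
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Per-segment step-time intervals for both devices over matched events."""
    res = match_events(imu_events, footswitch, tol=tol)
    imu_iv: list[np.ndarray] = []
    ref_iv: list[np.ndarray] = []
    pairs = res.pairs
    if not pairs:
        return imu_iv, ref_iv
    imu_idx = np.array([i for i, _ in pairs])
    ref_idx = np.array([j for _, j in pairs])
    # consecutive matched pairs within the same IMU segment and the same
    # reference trial yield one interval per device
    for seg in np.unique(imu_events.trial[imu_idx]):
        m = imu_events.trial[imu_idx] == seg
        ii, jj = imu_idx[m], ref_idx[m]
        same_ref_trial = footswitch.trial[jj[1:]] == footswitch.trial[jj[:-1]]
        consecutive = (np.diff(ii) == 1) & (np.diff(jj) == 1) & same_ref_trial
        di = np.diff(imu_events.times[ii])[consecutive]
        dr = np.diff(footswitch.times[jj])[consecutive]
        if di.size:
            imu_iv.append(di)
            ref_iv.append(dr)
    return imu_iv, ref_iv


def cohort_outcomes(
    dataset,
    params: DetectionParams = DetectionParams(),
    max_events: int = MAX_EVENT_COUNT,
    tol: float = 0.050,
    reg_weight: float = 1e-3,
) -> tuple[pd.DataFrame, StepLengthModel | None]:
    """Run the full pipeline over a simulated cohort.

    Returns the long outcome table (subject, group, condition, device,
    measure, value) with device in {smartmove, reference}, plus the fitted
    step-length calibration model (None when too few walkway steps exist).
    The reference device is the footswitch for step-time measures and the
    walkway for step-length measures.
    """
    analyses: dict[tuple[str, str], list[TrialAnalysis]] = {}
    for cell in dataset.cells:
        analyses[(cell.subject, cell.condition)] = [
            analyze_recording(rec, params) for rec in cell.recordings
        ]

    # one cohort-wide step-length calibration on walkway-matched steps
    all_an, all_ww, all_subj = [], [], []
    for cell in dataset.cells:
        for analysis, walkway in zip(analyses[(cell.subject, cell.condition)], cell.walkway):
            all_an.append(analysis)
            all_ww.append(walkway)
            all_subj.append(cell.subject)
    X, y, labels = collect_length_training(all_an, all_ww, all_subj, tol=tol)
    model = None
    if len(y) >= 20:
        model = fit_step_length_model(X, y, reg_weight=reg_weight, subjects=labels)

    rows = []
    for cell in dataset.cells:
        cell_analyses = analyses[(cell.subject, cell.condition)]
        base = {"subject": cell.subject, "group": cell.group, "condition": cell.condition}

        imu_time_iv: list[np.ndarray] = []
        ref_time_iv: list[np.ndarray] = []
        imu_len_iv: list[np.ndarray] = []
        ref_len_iv: list[np.ndarray] = []
        for analysis, fsw, ww in zip(cell_analyses, cell.footswitch, cell.walkway):
            iv_i, iv_r = _matched_time_intervals(analysis.events, fsw, tol)
            imu_time_iv.extend(iv_i)
            ref_time_iv.extend(iv_r)
            if model is not None:
                pairs = _matched_step_pairs(analysis.events, ww, tol)
                if pairs:
                    feats = []
                    refs = []
                    for t_i, t_j, L in pairs:
                        try:
                            feats.append(step_features(analysis.signal, t_i, t_j))
                        except ValueError:
                            continue
                        refs.append(L)
                    if feats:
                        imu_len_iv.append(model.predict(np.array(feats)))
                        ref_len_iv.append(np.array(refs))

        for device, kind, lists in (
            ("smartmove", "time", imu_time_iv),
            ("reference", "time", ref_time_iv),
            ("smartmove", "length", imu_len_iv),
            ("reference", "length", ref_len_iv),
        ):
            series = build_delta_series(lists, kind=kind, max_events=max_events)
            if len(series) < 2:
                continue
            om = outcome_measures(series)
            prefix = "step_time" if kind == "time" else "step_length"
            rows.append({**base, "device": device,
                         "measure": f"{prefix}_delta_M", "value": om.delta_M})
            rows.append({**base, "device": device,
                         "measure": f"{prefix}_delta_CV", "value": om.delta_CV})
    return pd.DataFrame(rows), model
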