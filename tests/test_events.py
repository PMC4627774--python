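"""Heel-strike analogue detection, turn exclusion, foot side, matching."""

import numpy as np
import pytest

from stridelab.events import (
    DetectionParams,
    ParameterError,
    TooShortError,
    classify_foot_side,
    detect_heel_strike_analogues,
    exclude_turn_segments,
    match_events,
    preprocess,
)
from stridelab.imu_io import BodyFrameSignal, GaitEventSeries, to_body_frame
from stridelab.synthetic import GaitProfile, simulate_step_sequence, simulate_trial, synthesize_imu

FS = 100.0


def _signal(n, fs=FS, **channels):
    t = np.arange(n) / fs
    z = np.zeros(n)
    kw = {k: channels.get(k, z).copy() if isinstance(channels.get(k, z), np.ndarray) else z
          for k in ("a_AP", "a_UD", "a_LR", "w_AP", "w_UD", "w_LR")}
    for k, v in channels.items():
        kw[k] = np.asarray(v, dtype=float)
    return BodyFrameSignal(t=t, fs=fs, **kw)


def _series(times, trial=None):
    times = np.asarray(times, dtype=float)
    return GaitEventSeries(
        times=times,
        feet=("unknown",) * len(times),
        device="smartmove",
        trial=np.zeros(len(times), int) if trial is None else np.asarray(trial, int),
    )


class TestPreprocess:
    def test_dc_rejected(self):
        sig = _signal(1000, a_UD=np.full(1000, 9.81))
        out = preprocess(sig)
        assert np.max(np.abs(out.a_UD)) < 1e-6

    def test_passband_tone_preserved_without_phase_lag(self):
        t = np.arange(3000) / FS
        tone = np.sin(2 * np.pi * 1.8 * t)
        out = preprocess(_signal(3000, a_UD=tone))
        mid = slice(500, 2500)  # avoid filter edges
        amp = np.max(np.abs(out.a_UD[mid]))
        assert amp == pytest.approx(1.0, rel=0.02)
        # zero-phase: the filtered peak stays on the input peak's sample
        # (compare within one cycle; the tone has many equal maxima)
        ip = 500 + int(np.argmax(tone[mid]))
        cycle = slice(ip - 13, ip + 14)  # one quarter-period each side
        op = cycle.start + int(np.argmax(out.a_UD[cycle]))
        assert abs(ip - op) <= 1

    def test_high_frequency_noise_attenuated_20db(self):
        t = np.arange(3000) / FS
        carrier = np.sin(2 * np.pi * 2.0 * t)
        noise = 0.5 * np.sin(2 * np.pi * 30.0 * t)
        out = preprocess(_signal(3000, a_UD=carrier + noise))
        spec_in = np.abs(np.fft.rfft(carrier + noise))
        spec_out = np.abs(np.fft.rfft(out.a_UD))
        freqs = np.fft.rfftfreq(3000, 1 / FS)
        band = (freqs > 29) & (freqs < 31)
        atten_db = 20 * np.log10(spec_in[band].max() / spec_out[band].max())
        assert atten_db >= 20

    def test_too_short_raises(self):
        with pytest.raises(TooShortError):
            preprocess(_signal(10))

    def test_invalid_band_raises(self):
        with pytest.raises(ParameterError):
            preprocess(_signal(1000), DetectionParams(band=(8.0, 0.3)))


class TestDetection:
    def _detect_clean(self, n_steps=19, seed=1):
        truth = simulate_step_sequence(GaitProfile(group="HE"), n_steps, seed=seed)
        rec = synthesize_imu(truth, snr_db=100.0, seed=seed + 1)
        body = preprocess(to_body_frame(rec))
        return truth, detect_heel_strike_analogues(body)

    def test_zero_noise_recovers_every_event_within_one_sample(self):
        truth, events = self._detect_clean()
        assert len(events) == len(truth.event_times)
        np.testing.assert_allclose(events.times, truth.event_times, atol=1.0 / FS)

    def test_constant_signal_yields_empty_series(self):
        sig = _signal(1000, a_UD=np.full(1000, 3.0))
        assert len(detect_heel_strike_analogues(sig)) == 0

    def test_noisy_pd_trace_recall_precision(self):
        truth = simulate_step_sequence(GaitProfile(group="PD", mean_step_time=0.6,
                                                   step_time_cv=4.0), 40, seed=3)
        rec = synthesize_imu(truth, snr_db=6.0, seed=4)
        body = preprocess(to_body_frame(rec))
        events = detect_heel_strike_analogues(body)
        ref = _series(truth.event_times)
        res = match_events(events, ref, tol=0.050)
        recall = res.n_matched / len(ref)
        precision = res.n_matched / len(events)
        assert recall >= 0.95 and precision >= 0.95

    def test_count_invariant_to_offset_and_positive_scaling(self):
        truth, events = self._detect_clean()
        rec = synthesize_imu(truth, snr_db=100.0, seed=2)
        body = preprocess(to_body_frame(rec))
        for transform in (lambda x: x + 5.0, lambda x: 3.7 * x, lambda x: 0.2 * x - 1.0):
            mod = BodyFrameSignal(t=body.t, a_AP=body.a_AP, a_UD=transform(body.a_UD),
                                  a_LR=body.a_LR, w_AP=body.w_AP, w_UD=body.w_UD,
                                  w_LR=body.w_LR, fs=body.fs)
            assert len(detect_heel_strike_analogues(mod)) == len(events)


class TestTurnExclusion:
    def test_no_yaw_keeps_everything(self):
        sig = _signal(2000)
        ev = _series(np.linspace(1, 18, 20))
        out = exclude_turn_segments(ev, sig)
        assert len(out) == 20

    def test_turn_removes_guard_neighbours_and_splits_segments(self):
        truth = simulate_trial(GaitProfile(group="HE"), "self", seed=3)
        rec = synthesize_imu(truth, snr_db=100.0, seed=4)
        body = to_body_frame(rec)
        ev = _series(truth.event_times)
        out = exclude_turn_segments(ev, body, DetectionParams(turn_guard_steps=1))
        # the 2-s turn has no events inside; guard=1 drops one event each side
        assert len(out) == len(truth.event_times) - 2
        assert len(np.unique(out.trial)) == 2

    def test_threshold_above_max_yaw_is_noop(self):
        truth = simulate_trial(GaitProfile(group="HE"), "self", seed=5)
        rec = synthesize_imu(truth, snr_db=100.0, seed=6)
        body = to_body_frame(rec)
        ev = _series(truth.event_times)
        out = exclude_turn_segments(ev, body, DetectionParams(turn_yaw_threshold=99.0))
        np.testing.assert_array_equal(out.times, ev.times)

    def test_never_increases_or_reorders(self):
        truth = simulate_trial(GaitProfile(group="PD"), "self", seed=7)
        rec = synthesize_imu(truth, snr_db=12.0, seed=8)
        body = to_body_frame(rec)
        ev = _series(truth.event_times)
        out = exclude_turn_segments(ev, body)
        assert len(out) <= len(ev)
        assert np.all(np.diff(out.times) > 0)


class TestFootSide:
    def test_zero_noise_labels_match_truth(self):
        truth = simulate_step_sequence(GaitProfile(group="HE"), 19, seed=9)
        rec = synthesize_imu(truth, snr_db=100.0, seed=10)
        body = to_body_frame(rec)
        ev = _series(truth.event_times)
        out = classify_foot_side(ev, body)
        assert out.feet == truth.feet

    def test_zero_roll_gives_unknown(self):
        sig = _signal(2000)
        ev = _series([2.0, 2.5, 3.0])
        out = classify_foot_side(ev, sig)
        assert set(out.feet) == {"unknown"}

    def test_noisy_accuracy(self):
        truth = simulate_step_sequence(GaitProfile(group="PD"), 40, seed=11)
        rec = synthesize_imu(truth, snr_db=6.0, seed=12)
        body = to_body_frame(rec)
        out = classify_foot_side(_series(truth.event_times), body)
        acc = np.mean([a == b for a, b in zip(out.feet, truth.feet)])
        assert acc >= 0.95


class TestMatchEvents:
    def test_identical_series_fully_matched(self):
        a = _series([1.0, 1.5, 2.0])
        res = match_events(a, a, tol=0.05)
        assert res.n_matched == 3
        assert res.mean_error == 0.0 and res.sd_error == 0.0

    def test_constant_shift_reported(self):
        a = _series([1.0, 1.5, 2.0])
        b = _series([0.99, 1.49, 1.99])
        res = match_events(a, b, tol=0.05)
        assert res.n_matched == 3
        assert res.mean_error == pytest.approx(0.010, abs=1e-12)

    def test_missing_candidates_count_unmatched_reference(self):
        ref_times = 1.0 + 0.55 * np.arange(20)
        cand_times = np.delete(ref_times, np.arange(4, 20, 5))  # drop every 5th
        res = match_events(_series(cand_times), _series(ref_times), tol=0.05)
        assert res.unmatched_reference == 20 // 5
        assert res.unmatched_candidate == 0

    def test_one_to_one_bound(self):
        rng = np.random.default_rng(13)
        a = _series(np.sort(rng.uniform(0, 10, 30)))
        b = _series(np.sort(rng.uniform(0, 10, 17)))
        res = match_events(a, b, tol=0.3)
        assert res.n_matched <= min(len(a), len(b))
        matched_refs = [j for _, j in res.pairs]
        assert len(matched_refs) == len(set(matched_refs))

    def test_nonpositive_tol_rejected(self):
        a = _series([1.0])
        with pytest.raises(ParameterError):
            match_events(a, a, tol=0.0)
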