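# stridelab

Gait and gait-variability analysis from a trunk-worn smartphone IMU, for
researchers and clinicians studying Parkinson's disease (PD) and rhythmic
auditory cueing (RAC).

Elevated step-to-step variability — quantified by second-moment statistics of
step times and step lengths — is a marker of fall risk in PD, and walking to a
metronome reliably reduces it. Measuring it normally requires heel-mounted
footswitches or an instrumented pressure walkway. `stridelab` implements the
alternative: a single 100-Hz tri-axial accelerometer + gyroscope worn at the
navel, analyzed end to end, together with the statistical framework that puts
the device's measurement error in context.

## What it computes

For each subject × cueing condition (self-paced, 100% RAC, 110% RAC) × device,
the pipeline produces a **Δ-series** — the pooled sequence of inter-step times
(s) or step lengths (m), concatenated across trials with no interval spanning
a trial boundary, capped at 50 values — and two outcome measures:

- **Δ_M** — the mean of the Δ-series (first-moment gait measure),
- **Δ_CV = 100 × Δ_SD / Δ_M** — the coefficient of variation in percent, where
  Δ_SD is the sample standard deviation (second-moment gait-variability
  measure).

The stages in between:

1. **imu_io** — reads six-channel IMU CSVs, validates the sampling rate, and
   relabels device axes into anatomical ones (a_AP = −a_z, a_UD = −a_y,
   a_LR = a_x; likewise for rotation rates).
2. **events** — zero-phase band-pass (0.3–8 Hz), heel-strike *analogue*
   detection as vertical-acceleration peaks, turn exclusion from the yaw rate,
   left/right foot labeling from the roll rate, and greedy one-to-one matching
   of detected events against reference-device events (footswitch, walkway) so
   both devices always summarize the same steps.
3. **spatiotemporal** — Δ-series and outcome measures; step lengths by
   drift-corrected double integration of anterior acceleration, calibrated to
   walkway reference lengths with a ridge regression evaluated
   leave-one-subject-out.
4. **rac** — cadence estimation from pooled step intervals and metronome cue
   schedules at 100%/110% of self-paced cadence.
5. **stats** — mixed-factorial repeated-measures ANOVA (Group between
   subjects; RAC and Device within) with subject-nested error strata, and
   classical eta-squared effect sizes

   η² = SS_effect / SS_total,

   labeled by the conventions ≈.02 small, ≈.13 medium, ≈.26 large. A device
   whose main effect and interactions stay small while Group/RAC effects are
   medium-to-large is measuring gait, not itself.
6. **synthetic** — a simulated cohort (12 PD-like + 12 healthy-elderly-like
   subjects, three conditions, a 26-m path with a mid-trial turn and a 7-m
   walkway window) with exact ground truth, so every stage is testable without
   any recordings.

## Worked example

```python
import stridelab as sl
from stridelab.spatiotemporal import build_delta_series, outcome_measures, step_time_intervals

profile = sl.GaitProfile(group="PD", mean_step_time=0.60, step_time_cv=4.0)
truth = sl.simulate_step_sequence(profile, n_steps=39, seed=11)
rec = sl.synthesize_imu(truth, snr_db=12.0, seed=12)       # 100-Hz recording

analysis = sl.analyze_recording(rec)                        # detect + label
series = build_delta_series(step_time_intervals(analysis.events), kind="time")
om = outcome_measures(series)
cadence = sl.mean_cadence(analysis.events)
cue = sl.metronome_schedule(cadence, relative_tempo=1.1, duration=10.0)
```

This prints (via the obvious f-strings):

```
detected events: 40 (truth: 40)
step time delta_M = 0.5985 s   delta_CV = 3.24 %   (n = 39)
truth     delta_M = 0.5985 s   delta_CV = 3.45 %
self-paced cadence = 100.3 steps/min -> 110% cue tempo = 110.3 bpm
```

At a 12-dB SNR every true heel strike is detected, the mean step time is
recovered to a fraction of a millisecond, and the variability estimate is
within a quarter percentage point of truth; the 110% cue schedule plays 10%
faster than the measured self-paced cadence.

The same flow is available from a shell:

```
stridelab --seed 7 --out-dir sim simulate --n-per-group 12
stridelab --out-dir out analyze sim/PD01_self_trial0_imu.csv
stridelab --out-dir out validate out/PD01_self_trial0_imu_events.csv sim/PD01_self_trial0_footswitch.csv
stridelab --out-dir out anova sim/expected_outcomes.csv --design group_rac_device
```

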