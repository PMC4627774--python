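# Methods

This note documents the models, numerical choices and open design decisions
behind `stridelab`, and what the synthetic cohort does and does not establish
about real recordings.

## Signal model and coordinate conventions

A recording is a uniformly sampled six-channel inertial signal at a nominal
100 Hz: device-frame accelerations (m/s², gravity included) and rotation rates
(rad/s). Validation requires strictly increasing timestamps, finite samples,
and a median sampling interval within ±5% of the nominal rate; violations are
errors, not warnings, because downstream timing claims depend on the rate.
Accelerations stored in g-units are converted on read (× 9.80665).

With the device strapped at the navel, screen toward the subject and audio
jack up, anatomical axes are a pure sign/relabel map of device axes:
a_AP = −a_z, a_UD = −a_y, a_LR = a_x, and identically for rotation rates
(ω_AP = roll, ω_UD = yaw, ω_LR = pitch). The map preserves the per-sample
vector norm; tests enforce this as a property.

## Event detection

Heel-strike analogues are peaks of the band-passed vertical (UD) acceleration.
Choices and rationale:

- **Filter**: order-4 Butterworth, 0.3–8 Hz, applied forward-backward
  (`sosfiltfilt`) so gravity/DC and high-frequency noise are removed with zero
  phase shift — event timing must not move. Signals shorter than about three
  filter lengths are rejected.
- **Detection channel**: UD is the standard trunk-accelerometry heel-strike
  analogue; AP is the fallback when UD has no band power (e.g. a degenerate
  channel).
- **Peak constraints**: refractory period 0.25 s (admits cadence up to
  4 steps/s); prominence at least 0.3 × the filtered signal's 5th–95th
  percentile range, which makes detection invariant to offsets and positive
  rescaling while tolerating the reduced amplitudes of parkinsonian gait.
  Plateau peaks are timestamped at their earliest sample.
- **Turn exclusion**: a subject turning mid-path produces no valid steps.
  Samples where the 0.5-s-smoothed |yaw rate| exceeds 0.6 rad/s define turn
  intervals; events inside an interval are dropped, along with one guard event
  on each side, and the survivors are re-grouped into straight segments that
  downstream interval construction treats as separate trials. Turn detection
  runs on the *unfiltered* yaw because the band-pass removes the near-DC
  plateau of a slow turn.
- **Foot side**: the mean roll rate in a ±150-ms window around an event tips
  toward alternate sides on alternate steps. Because strap placement flips the
  absolute polarity, the sign→side mapping is chosen per recording as the one
  maximizing within-segment alternation (ties keep positive→left). Windows
  with no roll energy are labeled unknown rather than guessed.
- **Matching**: concurrent-validity comparisons align detected events to
  reference events greedily by absolute time difference within 50 ms,
  one-to-one. Greedy-by-|Δt| is order-independent and auditable; at the timing
  errors observed here (≪ half a step period) it is equivalent to optimal
  assignment.

## Step lengths

The anterior acceleration over one step, integrated twice (trapezoid rule at
native sampling, no resampling), gives a raw displacement. Steady gait implies
the trunk's forward-velocity fluctuation returns to its step-start value at
the next heel strike, so the linear velocity trend implied by v(t_j) − v(t_i)
is subtracted before the second integration (per-step drift correction). This
recovers the oscillatory displacement, not the full step length, and sensor
noise inflates it stochastically; a ridge regression therefore calibrates
per-step features (raw displacement, step duration, RMS of AP and UD
acceleration, peak-to-peak UD) against reference step lengths from the
walkway, using only steps inside the walkway window. Ridge (default weight
1e-3 on standardized features) was chosen over fancier regressors because it
is deterministic, auditable, and sufficient at these feature counts; weight 0
falls back to least squares and refuses rank-deficient features. Model quality
is always reported leave-one-subject-out when subject labels exist, because
per-step residuals within a subject are not exchangeable. Predictions are
clipped to a physiological 0.05–2.5 m.

## Δ-series and outcome measures

Intervals are computed strictly within trials/segments, pooled across trials
in collection order, and truncated to the first 50 values per condition —
the cap keeps event counts comparable across subjects, and "first in
collection order" is the simplest deterministic rule. Δ_SD uses the n−1
denominator, standard for small samples and the CV literature.
Device-comparison series are built only from matched events, so the two
devices always have equal n.

## Cueing

Cadence is 60 × (number of pooled within-trial intervals) / (their summed
duration) — a pooled estimate, not an average of per-trial averages, so short
trials are not over-weighted. Cue schedules are arithmetic beat sequences
starting at t = 0 with no count-in; the 110% schedule's tempo is exactly 1.1 ×
the 100% schedule's by construction.

## Mixed-factorial ANOVA and η²

The designs are Group × RAC × Device (Group between subjects; RAC 3 levels and
Device 2 levels within), Group × Device at a single condition, and
RAC × Device within a single group. The decomposition is the classical
univariate repeated-measures one with subjects nested in Group: the
between-subjects stratum splits into Group and subject(Group); each
within-subject effect and its Group interaction are tested against that
factor's interaction-with-subject(Group) stratum. Moment formulas on marginal
means are used directly; with subjects fully crossed with the within factors,
cell counts are proportional even when group sizes differ, so the partition is
unambiguous. The test suite checks the partition against an independent
nested-least-squares oracle (1e-9 relative) and against two external
implementations on the designs they support, plus the classical F = t² paired
identity.

Eta-squared is **classical**: SS_effect / SS_total with SS_total including all
error strata, so SS_effect/η² is one constant per table — the published
tables this framework mirrors are mutually consistent only under a common
denominator (e.g. 0.0599/.248 ≈ 0.0589/.243 ≈ 0.242). Partial η² is not
reported. Conventions: < .02 negligible, .02–.13 small, .13–.26 medium,
≥ .26 large. No sphericity correction is applied by default, matching the
uncorrected published p-values; zero error variance flags F as infinite
rather than failing.

Casewise deletion removes any subject missing any condition × device cell of
the chosen design — imputation would add assumptions that repeated-measures
ANOVA cannot audit. Subject-level workbooks in wide format are ingested by
token-matching column headers (self/100/110 × device × measure); layouts that
cannot be parsed raise immediately rather than guessing.

Demographic comparisons use Welch's unequal-variance t-test.

## Synthetic cohort: what it emulates

Defaults are the study conditions: 12 + 12 subjects, three cueing conditions,
a 26-m path as two 13-m passes joined by one 2-s turn (yaw plateau
1.2 rad/s), trials repeated until ≥ 40 heel strikes land on the 7-m walkway
window, IMU at 100 Hz and SNR 12 dB, footswitch timing jitter SD 5 ms,
walkway length jitter SD 1 cm.

Group profiles (qualitative anchors, not published numbers): healthy-elderly
mean step time 0.55 s / CV 2%, step length 0.65 m / CV 2.5%; PD-like 0.60 s /
CV 4%, 0.50 m / CV 5%. Step durations and lengths are i.i.d. truncated normal
(±4 SD) with time–length correlation ρ = 0.3; CVs ≥ 40% are rejected as
non-physiological. Cueing entrains the mean perfectly (110% divides the mean
step time by 1.1 and lengthens steps by 5%) and shrinks CVs by a reduction
factor: 0.7 for the PD-like profile (strong benefit), 0.9 for the
healthy-elderly profile (mild benefit, consistent with their lower baseline
variability). Feet alternate strictly from a seeded random side.

The IMU trace is constructed in the body frame: a biphasic vertical pulse
(Gaussian main lobe σ = 30 ms, delayed negative rebound) peaking exactly at
each heel strike with amplitude growing with step length; per step, an
anterior full-period sine with amplitude 2πL/T², so its drift-corrected double
integral equals the true step length analytically (the trapezoid error at
100 Hz is well under 2%); roll bursts of alternating sign encode foot side;
the yaw plateau marks the turn. Channel-wise Gaussian noise is added at the
configured SNR relative to each clean channel's variance. All randomness
descends from one master seed through a spawned seed tree; regeneration is
bit-exact across processes.

**What passing tests do not show**: the synthetic trace has a single dominant
vertical peak per step, no soft-tissue or strap resonance, no freezing or
festination, no asymmetric pathology, and an anterior channel built to satisfy
the integrator's own assumption. Recovery results here validate the pipeline's
internal consistency and its statistical machinery, not its accuracy on
arbitrary real recordings; real-world accuracy is the province of the
concurrent-validity comparison against heel-contact devices.

## Numerical choices and degenerate inputs

- Detection on a constant signal returns an empty series (not an error);
  empty series propagate as insufficient-data errors only where a statistic
  becomes undefined (n < 2).
- Outcome measures require n ≥ 2; Δ_CV of a constant series is exactly 0.
- Zero within-stratum variance flags F = ∞ (effect present) or NaN (no
  effect), never a division crash.
- Event and IMU CSVs serialize at ≥ 9 significant digits so read→write→read
  is the identity to text precision.
- Matching tolerance 50 ms default; detection timestamps are exact sample
  times, so one sample period (10 ms) is the resolution floor quoted in
  recovery claims.
- The acceptance script's simulated study uses the default cohort scale
  (24 subjects, ~2 trials per condition), the package's own choice of a
  desk-scale problem size that still powers the Group/RAC/Device contrasts.

## Known limitations

- Step lengths outside the walkway window are produced but never validated
  against a reference; the device comparison uses matched-zone steps only.
- The greedy matcher can mis-pair events if two candidates fall within
  tolerance of one reference event and timing errors approach half a step
  period.
- Stride-level measures, stance/swing decomposition, detrended fluctuation
  analysis and frequency-domain measures are out of scope.
- The ANOVA is the univariate repeated-measures decomposition; mixed-effects
  (REML) formulations and post-hoc pairwise tests are not provided.
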