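# Methods

This note documents the models implemented in `mfv`, the choices made
where the device's published description leaves the algorithm open, and
what validation against the built-in simulator does and does not
establish.

## Session model and time base

All streams live on one session clock in **milliseconds since the first
sample of the earliest stream**.  Millisecond resolution is not cosmetic:
pulse arrival time is an interval of 150–350 ms measured *between two
sensors* (chest ECG, limb PPG), and a 1 mmHg change in systolic pressure
corresponds to only a few milliseconds of PAT.  The on-body network
synchronizes sensor clocks to about 1 ms; `SyncedSession.sync_tolerance_ms`
records that contract and `align()` models the removal of residual
per-sensor offsets (a pure time shift; a group action, so offsets
compose additively).

Native rates: chest ECG 512 Hz, high-rate IMU 416 Hz, accelerometer
vitals stream 52 Hz, temperature 0.2 Hz, PPG 256 Hz, Doppler 504 Hz,
EHG/abdominal ECG 500 Hz.

Missing samples are NaN.  Derived operations skip windows containing
gaps rather than interpolating silently.

File I/O: EDF for waveforms (implemented directly — 16-bit physical
scaling, multi-rate channels via per-channel samples-per-record; the
stream start time and true sample count ride in standard header fields),
long-format CSV (`time_ms,sensor,channel,value,units`) for both waveforms
and sparse references, 16-bit PCM WAV for Doppler audio.  EDF precision
is quantization-limited: the physical range is first rounded to its
8-character header representation, then sample error is at most one
quantum of (range / 2¹⁶).

## Maternal heart rate

QRS detection is a Pan–Tompkins-style chain: zero-phase band-pass
5–15 Hz (2nd-order Butterworth, forward–backward), derivative, squaring,
150 ms moving-window integration, then adaptive dual thresholds with
exponential signal/noise level tracking, a 200 ms refractory period, and
search-back at half threshold when an expected beat window (2 s) elapses.
Every constant is exposed in `PanTompkinsConfig` because the device's own
"modification" of the classic chain is not published; the defaults are the
classic adult values.  Two implementation details matter for timing
accuracy:

- the input is mirror-padded by 1 s so filter start-up transients cannot
  distort the first/last beats;
- each integration-peak detection is refined to the largest absolute
  band-passed excursion within ±150 ms, and when two refinements collide
  inside the refractory period the *stronger* peak wins (a weak candidate
  refined onto its window edge must not shadow the true R wave).

On noise-free simulated ECG this yields exactly one detection per beat,
within one sample of truth, for 50–200 bpm; at 10 dB SNR sensitivity and
precision stay ≥ 0.98.  Beats whose R–R interval leaves [250, 2000] ms or
whose local SNR is below 6 dB are flagged suspect, not deleted.

Heart rate is 60000 / mean(R–R) per sliding window (default 10 s window,
half-window step), using good beats only; fewer than two beats in a window
gives a missing value.  Values are kept unrounded; display rounding
(nearest integer for HR/FHR/RR, one decimal for SpO₂) is a view, applied
by `VitalSeries.display_values()`.  Note 60000/635 ms = 94.49 → displayed
94 bpm, while 60000/344 ms = 174.42 → displayed 174 bpm; a device report
of "170" for the latter interval cannot be reproduced by this formula at
any common rounding and we do not attempt to.

## SpO₂

Per window (default 10 s): pulse amplitude of each PPG channel is the
median peak-to-trough of the 0.5–8 Hz band-passed signal (peaks and
preceding troughs from a prominence-gated detector), DC is the window
mean, and

    R = (AC_red / DC_red) / (AC_ir / DC_ir),   SpO₂ = clamp(c₀ − c₁·R, 0, 100)

with defaults c₀ = 110, c₁ = 25 — a conventional empirical curve, exposed
as parameters because every oximeter front end carries its own factory
calibration; the device's coefficients are not public.  The upper clamp is
the one place a value is clipped rather than dropped: the linear map
exceeding 100% is an artifact of the curve, not a bad measurement.
Windows with nonpositive DC or no detectable pulses are missing.  Because
both channels share the pulse waveform shape, the shape factor cancels in
R, which is why the ratio-of-ratios is robust to morphology.

## Respiratory rate

Three estimators per window (default 60 s, minimum 30 s):

1. accelerometer x axis, band-passed 0.1–1.0 Hz, dominant periodogram
   frequency;
2. same for the y axis;
3. ECG-derived respiration: the R-peak amplitude series (beat-to-beat
   amplitude modulation), resampled to a uniform 4 Hz grid, dominant
   frequency in the same band.

An estimate is kept only if its spectral peak holds ≥ 20% of band power
(quality gate); the output is the quality-weighted median of the
survivors, in breaths/min.  The weighted-median fusion rule is this
package's choice — the device's exact fusion is not published — selected
because it is robust to one source failing (motion on one axis, low EDR
modulation) without averaging in its error.  The estimator is invariant
to DC offset and per-axis gain by construction (detrending + frequency
domain).  The 52 Hz accelerometer vitals stream is the default source;
the 416 Hz IMU stream can be decimated to it since the respiratory band
sits far below either Nyquist.

## Temperature

Moving-median smoothing (default 5 min window) of the direct 0.2 Hz
readings; chest (central) and limb (peripheral) channels stay separate.
The median rejects isolated contact artifacts while passing fever-curve
trends (a 2 °C/h ramp is preserved to < 0.05 °C).

## Fetal heart rate from Doppler

Each fetal cardiac cycle produces two audible valve closures: S1
(tricuspid/mitral) and S2 (pulmonary semilunar), 80–250 ms apart.  A naive
peak counter therefore reads double the true rate.  The pipeline:

1. **Envelope**: rectify, zero-phase low-pass at 25 Hz, at the native
   504 Hz.
2. **Period**: windowed autocorrelation of the mean-removed envelope
   (3.75 s window, 0.25 s step — cardiotocography convention).  Candidate
   lags are local maxima within 250–1000 ms (60–240 bpm); among peaks
   within 85% of the strongest, the **smallest lag** is chosen.  The full
   beat period aligns both the S1 and the S2 train with themselves, so the
   true period is the shortest near-maximal lag, while the S2→S1 partial
   alignment scores well below it.  Windows whose best normalized
   autocorrelation falls under 0.45 report a missing rate.
3. **Pairing**: envelope peaks are paired S1→S2 greedily under the gap
   prior, consulting the autocorrelation period to reject a "pair" whose
   gap is really a full period.  Beat time = S1 time.

FHR = 60000 / period.  On simulated sessions this tracks a 110→180 bpm
ramp within 3 bpm and never reports the doubled rate for gaps of
100–200 ms.  Doppler audio export normalizes to max |sample| = 1 and
keeps 504 Hz so playback reproduces the bedside sound.

## Uterine contractions (EHG)

The uterine electromyogram is read per channel as: decimate to 20 Hz
(filtering at 500 Hz with a 0.34 Hz corner would be numerically fragile),
band-pass 0.34–1.0 Hz — the established electrohysterography band; the
device description names no band — then a 60 s moving-RMS envelope.  Two
channels are fused by pointwise maximum (contractile activity appears on
whichever electrode pair is better coupled).  Events are segmented by a
baseline-adaptive threshold (median + 4×MAD of the fused envelope);
onset and offset are then refined to the **half-prominence crossings**,
which for a symmetric RMS window cross at the true burst boundaries, so
the 60 s smear does not bias onsets.  Events shorter than 30 s are
dropped; durations outside 30–300 s are flagged.  Detected counts are
invariant to common gain.  The optional mmHg mapping is a two-parameter
affine calibration (`gain`, `offset`) against a reference
tocodynamometer segment — "simple calibration" is all the device
specifies, and an affine map is the minimal realization; note the event
amplitude above baseline scales by gain only.

## Fetal ECG isolation

The abdominal biopotential is maternal ECG projection plus fetal ECG at
roughly one tenth the amplitude.  Cancellation is template subtraction:

- the maternal template is the **median beat** across all chest-detected
  R times (median, not mean, so incoherent fetal beats do not enter it),
  spanning ±60% of the median R–R (at least ±300 ms) so slow
  repolarization tails are inside it;
- the record is tiled into non-overlapping per-beat **cells** (midpoint to
  midpoint), and within each cell the template segment is subtracted with
  a per-beat least-squares fit on the template *and its time derivative* —
  the derivative is the first-order Taylor term that absorbs the
  fractional-sample misalignment between the 512 Hz chest grid and the
  500 Hz abdominal grid, which otherwise leaves slope-shaped residuals
  the size of a fetal R wave.  A small integer-lag search (±2 samples)
  aligns the template; the cell boundaries stay fixed so the tiling has
  no gaps and nothing is subtracted twice.  The first cell reaches back
  only 250 ms (past its own P wave): farther left the template holds the
  *previous* beat's T tail, which the record's first beat does not have.

Fetal R peaks are then detected on the residual with the same QRS chain
retuned to fetal physiology (band 12–45 Hz — the fetal complex is about
half the maternal width, so the higher band separates it from
cancellation ripple — 80 ms integration, 150 ms refractory, R–R
250–600 ms).  A final amplitude gate drops "beats" below 3% of the
maternal projection amplitude: a fetal R is ~10%, cancellation ripple
~1.5%, so the gate separates a genuinely fetus-free record (empty output)
from a real fetus.  Requires ≥ 10 maternal beats for the template.  On
simulated mixtures at the 0.1 amplitude ratio: recall ≥ 0.9 (measured
1.0) with maternal residual ≈ 1.5% ≪ 20% of the original at beat times.

Limitation: at maternal rates above ~100 bpm the widened template window
overlaps neighbor beats and cancellation degrades gracefully; the stated
validation regime is maternal ≈ 60–94 bpm.

## Pulse arrival time and blood pressure

PAT: each R peak is matched to the first PPG pulse peak **strictly**
after it and before the next R peak (a pulse exactly at the R time is not
matched; unmatched beats are skipped).  The concurrent HR comes from the
R–R interval ending at the beat.  The PPG fiducial is the pulse peak by
default (matching the device description); the foot
(pre-peak minimum) is available for robustness studies.

Model: `BP = a_pat·PAT + b_hr·HR + c`, fit separately for systolic and
diastolic pressure by ordinary least squares.  The additive HR term is
the minimal form consistent with "improved with the addition of HR"; it
can be disabled (`use_hr=False`), and whether the diastolic fit should
include HR is unstated — the same form is applied to both.  Two modes:

- **continuous**: regress beats in the first 50 s (default) of overlap on
  the reference interpolated to beat times — the protocol used against a
  continuous BP monitor;
- **cuff**: each cuff reading is matched to the mean PAT/HR within ±30 s;
  all matched readings are fit jointly and the intercept is then shifted
  so the mean residual at the reference times is exactly zero ("the
  necessary offsets", implemented as a per-subject mean-residual offset).
  With only two readings the HR term is dropped (underdetermined).

A design with no PAT/HR variation raises a degenerate-calibration error
rather than returning an arbitrary minimum-norm fit.  Predictions outside
40–280 mmHg become missing; output is median-smoothed (default 30 s).
Parameter recovery on synthetic linear worlds (σ = 2 mmHg, 300 beats):
median coefficient error < 10%, held-out RMSE ≤ 3 mmHg.  A simulated
cold-pressor epoch (PAT −15%, HR +10 bpm) raises predicted SBP on every
beat, reproducing the inverse PAT–BP relationship.  No re-calibration
scheduling is implemented; drift handling beyond the offset step is out
of scope.

## Posture

During quiet periods the accelerometer reads gravity in the sensor frame.
Samples are normalized to unit median magnitude (gain invariance), motion
gated (variance of the magnitude over 2 s windows < 0.02 g²), randomly
subsampled to 50,000 points (seeded), and fit with an 8-component
full-covariance Gaussian mixture (k-means++ initialization, 10 restarts,
EM tolerance 1e-6, fixed seed — bit-reproducible).  Each cluster mean is
then merged to a posture by nearest canonical gravity direction:

| posture | gravity direction (sensor frame) |
|---|---|
| supine | (0, 0, −1) |
| lateral | (±1, 0, 0) |
| hands–knees | (0, 0, +1) |
| high Fowler's | (0, −√½, −√½) (torso ≥ 45° up) |

The merge rule is geometric reconstruction — how the device's eight
clusters were translated to four postures is not published — and the
canonical vectors are configurable for other mounting conventions.
Classification is maximum-posterior; the reported confidence is the
posterior of the assigned *posture* (cluster posteriors pooled over the
merge map, so a posture covered by two overlapping clusters is not
spuriously uncertain).  Confidence < 0.6 or a failed motion gate yields
"unknown"; a 5 s median filter removes label flicker.  Per-posture vital
summaries exclude postures observed for under 60 s.

## Agreement and population analytics

**Bland–Altman**: device and reference series are paired nearest-neighbor
in time within a tolerance (default 5 s), each reference point used at
most once (closest claimant wins — the pairing rule is unstated in the
device's validation and this is the conservative choice).  Differences
are device − reference; limits of agreement are mean ± 1.96 × sample SD
(n−1).  The implementation is checked against brute-force recomputation
to 1e-9 and recovers injected (bias, SD) to ±0.03 at n = 10,000.

**Time-to-vital heat map**: sessions are pooled on their own session
clocks into a 2-D histogram (5 min time bins; value bins of 1 bpm for
HR/FHR, 1% SpO₂, 1 breaths/min, 2 mmHg for BP — bin widths are a
convention of this package).  A second matrix renormalizes each 4-hour
block of time columns to unit sum, up to 24 h, so the sparsely attended
later hours of long labors remain readable next to the dense first hours
(most monitored labors end within ~5 h).

**Session report**: a deterministic Markdown document (streams, seven
vital panels, contraction list, posture dwell fractions, QC counts);
absent sensors mark their panels absent rather than failing.

## The simulator and what green tests mean

`mfv.simulate` generates every stream from a declarative scenario:
Gaussian-sum PQRST templates at exact beat times (respiratory amplitude
modulation on the chest ECG), Gaussian pulse waves delayed by the true
PAT with AC/DC set to realize the requested ratio-of-ratios, Hann-windowed
100 Hz tone bursts for S1 (50 ms) and S2 (30 ms), band-limited-noise EHG
bursts under Hann envelopes, gravity-frame accelerometry per posture
schedule with a respiratory sinusoid, and piecewise-constant rate/PAT/BP
profiles.  All randomness flows from one seed; identical configs are
bit-identical.  Defaults state a plausible term pregnancy at rest:
maternal 80 bpm, fetal 140 bpm, PAT 250 ms, R = 0.5 (SpO₂ 97.5%),
15 breaths/min, 36.8 °C, fetal/maternal abdominal amplitude ratio 0.1,
noise zero unless a scenario adds it.

The simulator is a *timing-faithful* world, not a morphology-faithful
one.  It does not emulate real QRS morphology variation, electrode
motion artifacts, Doppler speckle or insonation-angle loss, overlapping
maternal/fetal spectra beyond amplitude scaling, baseline drift beyond a
single wander term, or arrhythmia.  A green test therefore establishes
that an algorithm is *correct* (right event, right time, right formula,
right invariances) under stated noise — not that it is clinically
validated.  The device's human-cohort agreement numbers depend on human
data and are intentionally not reproduced here.

## Numerical conventions

- Zero-phase filtering throughout (`sosfiltfilt`); detection chains
  mirror-pad 1 s at the edges.
- Sample SD (n−1) everywhere a spread is reported.
- Out-of-range derived values become NaN, never silently clipped (single
  exception: the SpO₂ upper clamp, see above).
- Ties in S1/S2 pairing break toward the autocorrelation-predicted
  period; refractory collisions in QRS refinement break toward the
  stronger peak.
- Long-duration validation (multi-hour BP drift) is run at one hour in
  the test suite for runtime economy; the generative model is stationary,
  so duration only narrows the standard error.
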