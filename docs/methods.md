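# Methods

This note documents the models, conventions, and design choices behind
`bgpipe`, in the spirit of a methods appendix: what each stage assumes,
which parameters matter (with units and defaults), what the synthetic
generator does and does not emulate, and where genuinely open design
questions were settled.

## Photometry conditioning

The pipeline assumes a two-channel recording on one uniform clock: a
calcium-dependent 465 nm signal F and a calcium-independent 405 nm
(isosbestic) control. Processing order:

1. **Decimation** — block-mean by an integer factor (default 10 for raw
   1017.3 Hz acquisitions, giving 101.73 Hz). Block averaging is used
   instead of naive subsampling so that out-of-band noise is attenuated
   rather than aliased.
2. **Trim** — the first `trim_s` seconds are dropped (default 180 s,
   configurable) to discard the LED/sensor settling period of real
   recordings.
3. **Isosbestic fit** — F0 is the least-squares affine map of the control
   onto the signal channel, `F0 = a·F405 + b`, fitted per session. For
   rotarod sessions the fit (and the percentile baseline below) is
   restricted to the pre/post rest epochs so the running epoch cannot
   deform the baseline; the fitted line is then evaluated everywhere.
   Because bleaching and motion artifacts are common to both channels,
   dividing them out via F0 removes both.
4. **dFF and robust z** — `dFF = 100·(F − F0)/F0` (guarded against
   non-positive F0 with an error listing offending samples) and
   `z = 0.6745·(dFF − median)/MAD`. The MAD is the raw median absolute
   deviation; the 0.6745 factor rescales it to a normal-consistent sigma
   estimate. The z trace has median exactly 0 by construction.

**Moving windows.** All moving windows (boxcar smoothing, running
percentile) use truncated — shrinking — windows at the edges, never
reflection padding: padding invents data at trial boundaries, which is
exactly where event-aligned analyses look. The 0.5 s moving average used
before peak counting is a centered boxcar; its frequency response is the
Dirichlet kernel, which the tests verify against the closed form.

**Baseline correction.** The moving 8th-percentile baseline has a default
window of 30 s (configurable). No window width is canonical for this
statistic; 30 s is long relative to single transients (≈1 s) and short
relative to bleaching, which is the regime in which the percentile tracks
drift without eating signal.

**Transient detection.** Local maxima with a minimum prominence of 0.5 z
and minimum separation of 0.2 s (both configurable; chosen to ignore noise
ripple while resolving the fastest behaviorally locked transients).
Amplitude is measured from the nearest preceding local minimum; AUC is the
trapezoidal integral divided by the epoch span `(n−1)/fs`; peak frequency
is `n_peaks / span`.

## Kinematics

**Coordinate convention.** Tracking tables arrive in image pixels with y
increasing downward. Calibration converts once to cm (arena corner = 42 cm,
rotarod height = 3 cm) and flips to y-up about the largest y in the table.
All downstream geometry — rotation sign (counter-clockwise positive), the
rotarod "height above the rod base" — assumes y-up; nothing downstream
re-flips.

**Cleaning.** Points with likelihood < 0.9 are replaced by shape-preserving
piecewise-cubic (PCHIP) interpolation over valid frames, clamped to the
nearest valid value at the edges; likelihoods themselves are preserved for
audit. PCHIP was chosen over a global spline because it cannot overshoot
on the steps and turns typical of pose traces.

**Speed.** Per-part speed is frame-to-frame displacement over the frame
interval. Body-center speed is additionally smoothed with a centered 2 s
boxcar. Bout detection runs at the native video rate (30 Hz): event
*times* (seconds) are what downstream alignment consumes, so nothing is
gained by resampling the speed trace first, and frame-exact onsets are
preserved. The 100 Hz upsampling exists to place coordinates on the
photometry grid when a common grid is required.

**Locomotor bouts.** A hysteresis rule: candidate epochs are maximal spans
with smoothed speed > 3 cm/s that reach 5 cm/s at least once. The onset is
the last local minimum (prominence > `flat_tol`, default 0.001 cm/s) in a
2 s look-back window before the upward 3 cm/s crossing; on a flat pre-bout
baseline, where no such minimum exists, the onset falls back to the latest
sample within `flat_tol` of the window minimum — the foot of the rise. The
offset is symmetric: the last local maximum before the final downward
5 cm/s crossing. The look-back bound (2 s) prevents the search from
escaping into a previous bout; `flat_tol` prevents numerical ripple from
masquerading as an extremum. A session already above 5 cm/s at frame 0
opens a bout at frame 0, flagged censored. Note that a centered boxcar of
width w shifts the detectable foot of a speed ramp w/2 earlier; analyses
comparing detected onsets with generative schedules must account for that
deterministic shift (the tests do so analytically).

**Rotarod jumps.** The vertical position of the lower body is robust-z
scored and jump onsets/offsets are the minima/maxima (prominence 0.5 z).
Quality gates: frames with likelihood ≤ 0.95 are dropped; runs of them
lasting ≥ 1 s split the trace into independently processed segments;
sessions with < 50 % of frames above 0.95 are excluded outright with a
dedicated exception.

**Motor states.** Locomotion: body-center speed > 4.5 cm/s. Motionless:
every tracked part ≤ 0.8 cm/s. Everything else: other (non-locomotor)
movement. The three labels are exhaustive and mutually exclusive per
frame; zone is periphery inside the outermost 10 cm band of the square
arena. Percent-time summaries are computed on native video frames.

**Rotations.** Per consecutive frame pair of normalized body vectors
(snout − lower body), the signed turn is
`atan2(x1·y2 − y1·x2, x1·x2 + y1·y2)` in degrees; cumulative rotation sums
from the stimulation onset. Frames where snout and lower body coincide are
skipped (zero contribution) and reported.

## Event-aligned statistics

Alignment slices the trace on its own grid around each event; events whose
window exceeds the trace are dropped and counted. Baseline normalization
subtracts the row mean over a stated window — (−5, −1) s before jump
onsets, (−15, −5) s before opto onsets — making the baseline-window mean
exactly zero per row.

**Lagged correlation.** Pearson r of `x[t]` against `y[t+k]` for every
integer-sample lag in ±5 s (default), computed on the overlapping,
shift-trimmed span — never zero-padded, since padding biases r toward 0.
The reported "best" correlation maximizes |r| (the signed value and lag are
reported); magnitude rather than signed maximization was chosen because
the scientific question is whether the signals share structure, whatever
the sign at the best lag. The implementation uses windowed moment sums
(after centering both series once, which Pearson ignores but float
arithmetic does not) and is verified against a brute-force per-lag scan.

**Phase-randomized surrogates.** Surrogates replace the phases of all
non-DC, non-Nyquist rFFT bins with uniform draws, preserving the amplitude
spectrum exactly — hence total power and autocorrelation (Wiener-Khinchin)
— while destroying phase alignment. The test compares the per-subject real
best correlations against one pooled population of `n_shuffle` (default
1000) surrogate best correlations, cycling through subjects, with a
two-sided Mann-Whitney rank-sum test; a per-subject surrogate mode exists
but pooling is the default because the real values form one population of
subjects and the surrogates one null population. Calibration is part of
the acceptance suite: with independent broadband inputs the rejection rate
at α = 0.05 sits in (0.03, 0.08) over 500 replicates.

**Duration coupling.** Jump durations (peak-to-peak of consecutive jump
onsets) are paired with transient durations (peak-to-peak of the matched
calcium peaks, each jump matched to its nearest peak within 2 s), pooled
across trials, and summarized by Pearson r. At least 3 pairs are required.

## Ephys

PSTHs use 1 ms half-open bins `[t, t+1)` spanning −1000 to +2000 ms; rate
per bin is the spike count across sweeps divided by `n_sweeps × 1 ms`.
Baseline statistics are taken over the 1000 pre-stimulation bins of the
summed PSTH: the mean, and the sample SD across bins (an alternative
per-sweep SD mode is deliberately not the default, because the
classification formula operates on the summed PSTH). Consequences worth
knowing: at 1 ms resolution Poisson counts make the baseline SD large, so
the ±2 z criterion is conservative — the measured false-positive rate on
null units is below 1 % — which matches its use as the "more stringent"
criterion alongside the ±1/3 rule.

The stimulation window is the full stimulation duration (250/500/1000 ms);
the 0 ms (no-light) condition is evaluated over 1000 ms post-onset so its
normalized rate is a genuine null control (≈1). A separate first-50 ms
window isolates the earliest response component. Units with zero baseline
are excluded from classification (no finite criterion applies) and counted
separately. Population tables count inhibited vs non-inhibited units per
region × drug × duration and test each drug contrast with Fisher's exact
test (scipy implementation, verified against hypergeometric enumeration in
the tests).

## Closed-loop replay

The online dFF differs from the offline chain by design: each channel is
baselined against a **trailing** 120 s mean (causal; NaN during warm-up
unless the shrinking-window flag is set), the control channel is
subtracted, and a first-order recursive low-pass at 1 Hz is applied
(`y[i] = (1−a)·x[i] + a·y[i−1]`, `a = exp(−2π·fc/fs)`). No output sample
depends on future input; the tests verify this by mutating samples after a
cut point and checking bit-identity before it.

The calcium trigger fires when the online signal has been above threshold
continuously for 250 ms and a local peak has occurred (detected causally as
a downturn), then adds the 200 ms mean compute latency; one trigger per
supra-threshold excursion, refractory enforced. The published threshold is
stated post hoc in robust-z units while the online stream is in raw dFF
units, so `threshold_from_zscore` maps a z target through the median/MAD
of a calibration epoch. The speed trigger requires rest (below 3 cm/s for
5 s; the terminal-silencing assay variant uses 2 s), a rise above 8 cm/s,
and 5 s during which speed never drops below the floor; the trigger lands
at the end of the sustain window. Speed is pre-averaged with a 1 s
trailing mean before comparison, since an "average speed threshold"
implies some averaging span and 1 s is the shortest that spans several
video frames. A scheduler turns accepted triggers into laser-on/off trials
under a 6 min inter-trial interval and per-condition caps, with alternating
or seeded-random assignment.

## Synthetic data

The generator produces the study conditions under which the pipeline is
validated; its defaults are fixed, not tuned per test.

| parameter | default | meaning |
|---|---|---|
| `fs_photometry` | 101.73 Hz | post-decimation photometry rate |
| `fs_video` | 30 Hz | video frame rate |
| `transient_rate` | 0.8 events/s | transient rate at reference speed |
| `tau_rise`, `tau_decay` | 0.07 s, 0.8 s | difference-of-exponentials kernel, slow-GCaMP-like |
| `bleach_tau` | 2000 s | shared exponential photobleaching |
| `noise_sd` | 0.3 a.u. | per-channel sensor noise (signal baseline 100 a.u.) |
| `coupling_gain` | 1.0 | speed → transient-rate modulation (speed scaled by 5 cm/s) |
| `artifact_gain` | 0.5 a.u. | SD of the motion artifact injected into both channels |
| `amp_mean`, `amp_cv` | 5 a.u., 0.3 | lognormal single-transient amplitudes |
| bout schedule | 8 s bouts each 60 s, peak 10 cm/s | trapezoid speed, 1 s ramps |
| `baseline_rate_hz` | 30 Hz | Poisson unit baseline |
| `inhibition_depth` | 0.8 | fractional rate suppression during stimulation |

Choices that deserve a word: the kernel time constants approximate a slow
GCaMP variant (no kernel is canonical, so the pair is a config parameter);
single-transient amplitudes have no published distribution, so the
lognormal and its CV are exposed rather than fixed; the default bout peak
of 10 cm/s represents a clear running bout — comfortably above both the
5 cm/s bout-entry threshold and the 8 cm/s closed-loop mobility threshold.
The open-field trajectory is a smoothly turning (circling) path so the
realized body-center speed equals the scheduled profile without
wall-collision artifacts; the rotarod trace is a triangle wave between the
rod base (0 cm) and top (3 cm), optionally with per-cycle period jitter so
jump durations have the variability that duration-coupling analyses need.
One integer seed drives everything through fixed per-component substreams,
so identical configs are bit-identical across runs.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: sensor saturation and nonlinearity,
hemodynamic contamination, non-exponential bleaching, pose-estimation
identity swaps and correlated tracking errors, grooming/rearing posture
dynamics (the synthetic mouse is never motionless, so the motionless state
is exercised by constructed cases instead), bursting or adapting spike
statistics, and real closed-loop actuation delays beyond a fixed latency.

## Problem sizes

The test suite and the acceptance script run on deliberately modest
problem sizes chosen to exercise every rule while keeping runs fast:
5–10-minute synthetic sessions, 3 seeds for segmentation recovery, 200
units for classification recovery, 500 replicates for the surrogate-test
calibration (8 subjects × 99 shuffles per replicate, 256-sample series),
and 20 coupled replicates for power. The full-scale defaults (1000
shuffles, 10-minute sessions) are used in the worked example and the
open-field/rotarod acceptance summaries.

## Numerical conventions and degenerate inputs

- Ties in flat extremum searches resolve to the **latest** sample.
- Spikes on bin edges go to the lower (left-closed) 1 ms bin.
- Constant inputs raise dedicated errors (degenerate fit for a constant
  control channel, degenerate scale for zero MAD, undefined correlation
  for zero-variance overlaps) rather than returning NaN silently.
- Events too close to trace edges are dropped and counted, never padded.
- Rank-sum p-values use the scipy implementation (exact for small
  tie-free samples, tie-corrected normal approximation otherwise).

## Known limitations

- The isosbestic fit is affine and per-session; slow gain drift between
  channels within a session is not modeled.
- Bout detection assumes the 2 s-smoothed speed; unsmoothed input
  violates the contract (the extremum refinement presumes a smooth trace).
- The online-dFF replay models the decision rules, not the acquisition
  hardware: lock-in demodulation, the online 3 Hz filter, and actuation
  jitter are out of scope.
- `epoch_correlation` reports the best-lag correlation per epoch; it does
  not correct for the multiple lags tested (the surrogate test is the
  calibrated significance path).
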