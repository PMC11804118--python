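# Methods

This note records the models, defaults and numerical choices behind
`epilfp`, and what the synthetic validation does and does not demonstrate.

## Signal model and conventions

A recording is a set of equal-length voltage channels sampled at `fs` Hz.
Storage unit is mV throughout: raw CSV/HDF5 values are divided by the
amplification gain once, at load time. Time is seconds from recording
start, samples are 0-based, and all analysis spans are half-open
`[t_start, t_end)`. Undefined statistics (e.g. the mean inter-spike
interval of a single spike) are NaN in memory and `null` in JSON — never
silently 0, which would be indistinguishable from a measurement.

## Spike detection

The detector implements three user-controlled thresholds.

*Moving amplitude threshold.* The analysis span is partitioned into
contiguous, non-overlapping windows of `win_len` (default 1.0 s; the final
window may be shorter), anchored at `t_start`. The threshold of window *w*
is `percent/100` times the maximum rectified amplitude in *w*. Windowed
recalculation tracks the considerable amplitude drift of epileptiform
spikes over a recording. Rectification (`polarity="both"`, the default)
treats negative-going deflections symmetrically, since LFP spikes can point
either way depending on electrode position relative to the generating
population; `positive`/`negative` restrict to one side.

*Fixed floor.* The per-sample effective threshold is
`max(window threshold, fixed_thr)`, so quiet windows cannot admit baseline
noise no matter how small their maximum.

*Temporal threshold.* Candidate events are maximal runs of consecutive
suprathreshold samples, each reduced to its extremum sample (a run crossing
a window boundary stays a single run, because thresholds are applied per
sample). Candidates are then accepted greedily in descending amplitude
order (ties: earlier time); a candidate is kept iff no kept spike lies
within `min_dist` of it. The keep-the-larger rule means a polyphasic
complex is counted once at its dominant deflection. The greedy pass is
equivalent to brute-force application of the same priority rule (tested
against an independent O(n²) oracle).

Summary statistics: amplitude max/mean/min over events, ISI max/mean/min
over consecutive event-time differences, and firing rate =
count / (t_end − t_start) in spikes per second.

Defaults (`percent=40`, `fixed_thr=0.1` mV, `min_dist=0.1` s) are the
standard working settings for cortical LFP from rodent epilepsy models.

## Filtering

Both designs target the 10–100 Hz band that empirically favours
threshold-based spike detection (slow drifts and fast noise removed).

* FIR: least-squares approximation of the ideal bandpass with ±5 Hz
  transition bands, multiplied pointwise by a Hann window to smooth the
  response. Default length is the smallest odd integer ≥ `fs` (a
  one-second impulse response — needed for a credible 10 Hz edge); the
  design-and-apply convenience caps it at ⌊len(signal)/4⌋ (odd, with a
  warning) for short signals.
* IIR: Butterworth bandpass, default order 4 per pass (effective 8 after
  the two passes).

Zero-phase application is literally forward filter → reverse → forward
filter → reverse. Edge transients are mitigated by odd-reflection padding
of `3×numtaps` (FIR) or `9×order` (IIR) samples, trimmed afterwards; each
pass is seeded with the filter's step-response steady state scaled to the
first padded sample, which keeps the startup transient inside the padding
even for the narrow-band IIR whose poles sit near the unit circle. The
procedure matches `scipy.signal.filtfilt` with identical padding to
~1e-10 (kept as an independent cross-check in the tests, not as the
implementation). Effective magnitude is the single-pass response squared;
phase is identically zero, so symmetric pulses keep their extremum sample.

## Morphology

Epochs of `half_width` (default 0.04 s, i.e. an 80 ms window covering the
upper bound of the 20–80 ms spike-duration definition; the trailing slow
wave is deliberately outside it) are cut around each detected peak; spikes
too close to an edge are dropped and counted. The pointwise mean is the
representative average spike. If detection ran on negative-going spikes,
the average is sign-flipped before slope analysis so the central peak is a
maximum.

Landmarks: the rising onset is the nearest local minimum before the
central peak, the descent end the nearest local minimum after it, falling
back to the window edges when none exists. The landmark search walks away
from the peak while the waveform keeps descending by more than a
hysteresis tolerance (2% of the waveform's peak-to-trough range;
tolerance 0 recovers the strict local-minimum rule). The hysteresis is a
deliberate robustness choice: on a flat pre-spike baseline the *strict*
nearest local minimum is a property of residual averaged noise, not of the
spike — smooth noise places it anywhere up to tens of ms before the true
onset, which corrupts the rising slope arbitrarily. With hysteresis the
walk stops at the first sub-tolerance stall, which on piecewise-linear
spikes is the true corner (and, conveniently, stopping anywhere on a
linear flank yields the same slope). Noiseless closed forms are unchanged.

Metrics: `rising = (v_peak − v_onset)/(t_peak − t_onset)`,
`descent = (v_end − v_peak)/(t_end − t_peak)` (negative for a falling
segment), and `overall` = mean of `|Δv|·fs` over consecutive samples on
the onset-to-end support. "Overall spike slope" admits several
definitions; the mean absolute instantaneous slope is this package's, and
for a triangle with rise `r` ms and fall `f` ms it equals the
duration-weighted mean of the two segment slopes.

## Coincidence

Events from two detection results are filtered to the analysis span and
matched one-to-one: candidate pairs with `|Δt| ≤ window` are admitted in
ascending `|Δt|` order (ties: earlier reference, then earlier comparison
time), skipping members already matched. One-to-one matching prevents a
dense comparison train from certifying one reference spike repeatedly. The
window is symmetric about each reference spike.

The headline percentage is `100·n_matched/n_ref` — per reference spike —
with the time-normalized alternative (`matched pairs per analyzed second`)
reported alongside, since "percentage over the analyzed period" admits
either reading. A span with zero reference spikes raises an explicit
undefined-percentage error rather than reporting 0%.

Greedy closest-first matching is maximum-cardinality whenever spikes
within each train are separated by more than twice the window (the
refractory regime of real spike trains, property-tested); a constructed
counterexample outside that regime (`ref=[0,1]`, `comp=[0.9,1.1]`,
`window=1`) is kept in the tests as a documented limitation.

## Correlation

Pearson's r with sample (n−1) normalization; the reported components
(means, sample sds) follow the same convention, which cancels in r. The
implementation evaluates the defining formula in its normalized
dot-product form `Σab/√(Σa²·Σb²)` on centered series, which is
algebraically identical and keeps `r(x, ±x) = ±1` exact in floating
point; results are clamped to [−1, 1]. Zero-variance series raise an
undefined-correlation error; in the k×k channel matrix such entries are
NaN, the rest form a symmetric matrix with unit diagonal. The two-channel
comparison generalizes to all channel pairs as a superset behavior.

## Synthetic data generator

The generator emulates exactly what threshold-based detection is sensitive
to, and nothing more:

* Baseline: white Gaussian innovations of sd `noise_sd`, low-pass shaped
  below 30 Hz with a zero-phase 4th-order Butterworth. `noise_sd`
  parameterizes the innovations; the shaped baseline's sd is smaller
  (≈0.24× at fs = 1000 Hz) because shaping removes most of the white
  power. The default `noise_sd=0.05` mV against 1-mV spikes leaves the
  smooth baseline well below the 0.1 mV floor, so detection errors reflect
  the algorithm, not irreducible noise overlap.
* Spikes: a piecewise-linear template (0 → amp over `rise_ms`, back to 0
  over `fall_ms`, defaults 10/20 ms, peak exactly `amp`), optionally
  followed by a half-sine slow wave. Placement is a Poisson process of
  rate `spike_rate` thinned to a refractory gap of template width + 20 ms,
  which guarantees planted spikes are individually resolvable so
  ground-truth matching is unambiguous.
* Pairs: each reference spike recurs on the comparison channel with
  probability `coincidence_p` at its time + N(0, `time_jitter_sd`);
  independent comparison-only spikes arrive at rate
  `spike_rate·(1 − coincidence_p)`. Coincident recurrences take precedence
  in refractory thinning; surviving recurrences are flagged on the
  reference train.
* Scoring: one-to-one matching within a tolerance (same rule as
  coincidence); precision of an empty detection and recall of an empty
  truth are NaN, not 0.

All randomness flows from the single integer seed; identical specs
produce bit-identical recordings.

What passing on this generator does **not** show: robustness to real LFP
backgrounds (1/f spectra, movement and chewing artifacts, electrical
interference), to spike-shape families beyond the piecewise-linear
template, to overlapping polyphasic discharges denser than the refractory
gap, or to non-stationary noise floors. The generator validates the
algorithmic contracts, not field performance.

## Problem sizes used in validation

The test suite and examples run at desk scale chosen to make the
statistics meaningful: single-channel recordings of 60 s at 1 kHz
(≈30 planted spikes) for detection and morphology recovery, 400 s pairs
(≈200 reference spikes) for coincidence so the binomial standard error of
the recovered percentage is ≈3.5 points, and 1000 randomized 2-s
recordings for the refractory-invariant sweep.

## Known limitations

* The moving threshold uses the rectified signal by default; recordings
  with strongly asymmetric baselines may prefer an explicit polarity.
* Greedy coincidence matching can fall below maximum cardinality when
  inter-spike intervals are shorter than twice the coincidence window
  (see above).
* Morphology measures only the averaged spike; per-spike morphology and
  slow-wave quantification are out of scope.
* EDF support trusts the file header for sampling rate and labels and
  expects calibrated physical units; CSV/HDF5 are the first-class formats.
* No seizure (ictal-period) detection, spike-subtype classification,
  lagged cross-correlation/coherence, or streaming mode.
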