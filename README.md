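# epilfp

Headless, scriptable analysis of epileptiform activity in local field
potential (LFP) recordings from epilepsy animal models. The package covers
the standard interictal-spike workflow — adaptive spike detection,
zero-phase bandpass filtering, average-spike morphology, inter-channel
spike coincidence, and Pearson correlation — as an importable Python
library, a set of narrative `examples/`, and a thin `epilfp` command-line
interface whose subcommands chain into a pipeline
(`simulate → filter → detect → morph / coincide / correlate`).

It is written for electrophysiologists who need reproducible, batchable
spike statistics (counts, amplitudes, inter-spike intervals, firing rates,
cross-regional synchrony) rather than an interactive GUI.

## The methods

**Three-threshold spike detection.** Epileptiform spikes are sharp
transients of 20–80 ms whose amplitude varies considerably over a
recording, so a single fixed threshold tracks them poorly. Detection
combines:

1. a *moving amplitude threshold*: within each 1-s analysis window the
   threshold is `percent/100 ×` the maximum rectified amplitude observed in
   that window (with 60% and a 1 mV window maximum, the threshold for that
   window is 0.6 mV);
2. a *fixed amplitude floor* (mV) guaranteeing a minimum acceptable spike
   amplitude in quiet windows;
3. a *temporal threshold*: a minimum allowed distance between consecutive
   accepted spikes, enforced greedily in descending amplitude order so a
   polyphasic complex counts once at its dominant deflection.

Each suprathreshold run of samples is reduced to its extremum; the result
carries the events plus max/mean/min amplitude, max/mean/min inter-spike
interval, and the firing rate over the analyzed span.

**Zero-phase bandpass filtering.** Recordings are band-limited to
10–100 Hz before detection, by a least-squares FIR design smoothed with a
Hann window or a Butterworth IIR design, applied forward → reversed →
filtered again → reversed. The two passes square the magnitude response
and cancel the phase response, so spike peaks are not displaced.

**Morphology.** Epochs of ±40 ms around each detected peak are averaged
into the representative spike; three slopes are measured on it: rising
(onset → peak), descent (peak → descent end, negative), and overall (mean
absolute per-sample slope over the spike support).

**Coincidence.** Given detections on a reference and a comparison channel,
spikes within a time window `w` of each other are matched one-to-one
(closest offsets first) and the percentage of matched reference spikes is
reported.

**Correlation.** Pearson's
`r = Σ(aᵢ−â)(bᵢ−b̂) / ((n−1)·σ_A·σ_B)` between channel pairs over a chosen
span, as a symmetric coefficient matrix with an optional heat-map PNG.

**Synthetic ground truth.** Because no public benchmark recordings exist
for this preparation, `epilfp.synth` generates LFP-like signals — a
low-frequency Gaussian baseline plus planted piecewise-linear spikes with
known times, amplitudes and cross-channel coincidence — and scores any
detection against them (precision/recall/F1).

## Worked example

`python examples/detect_spikes.py` simulates 60 s of LFP with planted
1-mV spikes (baseline noise sd 0.05 mV) and detects them with the standard
settings — moving threshold 40%, fixed floor 0.1 mV, minimum distance
0.1 s:

```
planted spikes : 34
detected spikes: 34
amplitude mV   : max 1.016  mean 0.995  min 0.974
ISI s          : max 5.91  mean 1.69  min 0.11
firing rate    : 0.567 spikes/s
vs ground truth: precision 1.000  recall 1.000  F1 1.000
```

Every planted spike is recovered within 10 ms and nothing else crosses the
three thresholds. The other examples exercise filtering (in-band gain
1.0000 at 50 Hz, 0.0000 at 1 and 300 Hz), morphology
(`rising 99.99 mV/s, descent −49.73 mV/s` against analytic +100/−50 for
the planted triangle), coincidence (59.2% detected for a planted 57.7%),
and the correlation matrix (measured ctx–hpc r = 0.498 against a
closed-form 0.505).

The same pipeline runs from the shell:

```sh
epilfp simulate --seed 42 --duration 60 --outdir out
epilfp detect --in out/sim_recording.csv --animal R01 \
    --percent 40 --fixed 0.1 --mindist 0.1 --outdir out
epilfp morph --detection out/detection_R01_ref.json \
    --in out/sim_recording.csv --outdir out
```

Results are JSON documents with an `experiment` section (animal, group,
sampling frequency, gain) and an `analysis` section (parameters and
outputs), auto-named `{analysis}_{animal}[_{channel}].{ext}` so runs never
overwrite each other across animals or channels.

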