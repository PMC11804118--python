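"""Pearson correlation matrix across channels.

Builds a three-channel recording in which channels A and B share a common
10 Hz oscillation plus independent noise, while channel C is pure noise.
For signal variance s^2 and noise variance n^2 the expected correlation
between A and B is s^2 / (s^2 + n^2); A-C and B-C should sit near zero.
Also writes the heat-map figure.
"""

import numpy as np

import epilfp

fs, dur = 1000.0, 30.0
rng = np.random.default_rng(42)
t = np.arange(int(fs * dur)) / fs
shared = 1.0 * np.sin(2 * np.pi * 10 * t)     # variance 0.5
noise_sd = 0.7                                 # variance 0.49

meta = epilfp.RecordingMetadata(
    experiment_name="demo", animal_id="R01", n_channels=3, fs=fs)
recording = epilfp.Recording(
    metadata=meta, channel_labels=["ctx", "hpc", "noise"],
    data=np.vstack([shared + rng.normal(0, noise_sd, t.size),
                    shared + rng.normal(0, noise_sd, t.size),
                    rng.normal(0, noise_sd, t.size)]))

result = epilfp.correlation_matrix(recording)
expected = 0.5 / (0.5 + noise_sd**2)
print("channels:", result.channel_labels)
for row, label in zip(result.matrix, result.channel_labels):
    print(f"{label:>6}: " + "  ".join(f"{v:+.3f}" for v in row))
print(f"expected ctx-hpc correlation: {expected:+.3f}")

epilfp.plot_correlation(result, "correlation_R01.png")
print("heat map written to correlation_R01.png")
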