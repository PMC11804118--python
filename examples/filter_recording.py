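"""Zero-phase 10-100 Hz bandpass filtering.

Builds a test signal from three sinusoids (1 Hz drift, 50 Hz in-band
component, 300 Hz noise), filters it with the default FIR design applied
forward-reverse-forward-reverse, and prints how much of each component
survives. The in-band component should pass nearly untouched and keep its
phase; the out-of-band components should essentially vanish.
"""

import numpy as np

import epilfp

fs = 1000.0
t = np.arange(int(10 * fs)) / fs
components = {1.0: 0.5, 50.0: 1.0, 300.0: 0.3}  # Hz -> amplitude (mV)
signal = sum(a * np.sin(2 * np.pi * f * t) for f, a in components.items())

spec = epilfp.design_bandpass("fir", fs)  # least-squares FIR, Hann-smoothed
print(f"designed {spec.kind} bandpass {spec.low:g}-{spec.high:g} Hz, "
      f"{spec.numtaps} taps")

filtered = epilfp.apply_zero_phase(signal, spec)

interior = slice(int(2 * fs), int(8 * fs))
for f, a in components.items():
    probe = a * np.sin(2 * np.pi * f * t)
    out = epilfp.apply_zero_phase(probe, spec)
    gain = np.sqrt(np.mean(out[interior] ** 2) / np.mean(probe[interior] ** 2))
    print(f"{f:6.0f} Hz component: amplitude gain {gain:.4f}")
# Gains near 1 inside 10-100 Hz and near 0 outside show the band-pass did
# its job; zero-phase application means spike peaks are not shifted in time.
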