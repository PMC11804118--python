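"""Average-spike morphology after detection.

The simulator plants triangular spikes rising 0 -> 1 mV in 10 ms and
falling back in 20 ms, so the analytic slopes are +100 mV/s (rising),
-50 mV/s (descent) and (100*10 + 50*20)/30 = 66.7 mV/s (overall mean
absolute slope). The detect -> morphology chain should recover these from
noisy data.
"""

import epilfp

spec = epilfp.SynthSpec(duration=60.0, noise_sd=0.05, spike_rate=0.5,
                        amp=1.0, rise_ms=10, fall_ms=20, seed=42)
recording, _ = epilfp.simulate_channel(spec)

detection = epilfp.detect_spikes(
    recording, "ref",
    epilfp.DetectionParams(percent=40, fixed_thr=0.1, min_dist=0.1))

morph = epilfp.analyze_morphology(recording, "ref", detection)

print(f"epochs averaged : {morph.n_epochs} (dropped {morph.n_dropped} at edges)")
print(f"rising slope    : {morph.rising_slope:8.2f} mV/s  (analytic +100)")
print(f"descent slope   : {morph.descent_slope:8.2f} mV/s  (analytic  -50)")
print(f"overall slope   : {morph.overall_slope:8.2f} mV/s  (analytic 66.7)")
print(f"spike support   : {morph.onset_offset*1e3:.0f} ms .. "
      f"+{morph.end_offset*1e3:.0f} ms around the peak")
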