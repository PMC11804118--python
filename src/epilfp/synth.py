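"""Synthetic LFP generator with known ground truth.

No public benchmark recordings exist for this kind of rodent epilepsy LFP,
so validation runs on simulated signals: a low-frequency Gaussian baseline
with piecewise-linear sharp transients (optionally followed by a slow
wave) planted at known times. The generator emits the planted times,
amplitudes and cross-channel coincidence flags, and a scorer turns a
detection run against that ground truth into precision/recall/F1.

All randomness flows from the single ``seed`` in the spec: identical specs
produce bit-identical recordings.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
from scipy import signal as sps

from .coincidence import match_events
from .io import Recording, RecordingMetadata

__all__ = [
    "SynthSpec",
    "GroundTruth",
    "spike_template",
    "simulate_channel",
    "simulate_pair",
    "score_detection",
]

#: extra refractory margin beyond the template width, seconds — keeps
#: planted spikes individually resolvable for unambiguous scoring
PLACEMENT_MARGIN_S = 0.02
#: corner frequency of the baseline shaping low-pass, Hz
BASELINE_LOWPASS_HZ = 30.0


@dataclass
class SynthSpec:
    """Parameters of one synthetic recording.

    noise_sd
        Standard deviation (mV) of the white Gaussian innovations that are
        then low-pass shaped below 30 Hz to form the baseline. The shaped
        baseline has a smaller sd (about 0.24x at fs=1000) because shaping
        removes most of the white power.
    spike_rate
        Poisson rate of planted spikes, spikes/s; thinned to enforce a
        refractory gap of template width + 20 ms.
    amp, amp_jitter_sd
        Template peak amplitude in mV and the sd of its per-spike Gaussian
        jitter.
    rise_ms, fall_ms
        Template segment durations; defaults 10/20 ms sit inside the
        20-80 ms epileptiform-spike duration definition.
    slow_wave
        Optional ``(amplitude_mV, duration_ms)`` half-sine appended after
        the sharp transient.
    coincidence_p, time_jitter_sd
        For paired simulation: probability that a reference spike recurs on
        the comparison channel, and the sd (s) of its timing jitter.
    """

    fs: float = 1000.0
    duration: float = 60.0
    noise_sd: float = 0.05
    spike_rate: float = 0.5
    amp: float = 1.0
    amp_jitter_sd: float = 0.0
    rise_ms: float = 10.0
    fall_ms: float = 20.0
    slow_wave: Optional[tuple[float, float]] = None
    coincidence_p: float = 0.6
    time_jitter_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be > 0")
        for name in ("noise_sd", "spike_rate", "amp", "amp_jitter_sd",
                     "rise_ms", "fall_ms", "time_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.coincidence_p <= 1:
            raise ValueError("coincidence_p must be in [0, 1]")
        refr = self.refractory_s
        if self.spike_rate * refr >= 1.0:
            raise ValueError(
                f"spike_rate={self.spike_rate}/s is infeasible with a "
                f"refractory gap of {refr:.3f} s"
            )

    @property
    def template_width_s(self) -> float:
        w = (self.rise_ms + self.fall_ms) / 1000.0
        if self.slow_wave is not None:
            w += self.slow_wave[1] / 1000.0
        return w

    @property
    def refractory_s(self) -> float:
        return self.template_width_s + PLACEMENT_MARGIN_S

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["slow_wave"] is not None:
            d["slow_wave"] = list(d["slow_wave"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SynthSpec":
        d = dict(d)
        if d.get("slow_wave") is not None:
            d["slow_wave"] = tuple(d["slow_wave"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted spike times/amplitudes per channel, plus per-reference-spike
    coincidence flags for paired simulations."""

    true_times: dict[str, list[float]]
    true_amps: dict[str, list[float]]
    coincident_flags: Optional[list[bool]] = None

    def times(self, channel: str) -> np.ndarray:
        return np.asarray(self.true_times[channel], dtype=float)


def spike_template(
    fs: float,
    rise_ms: float = 10.0,
    fall_ms: float = 20.0,
    amp: float = 1.0,
    slow_wave: Optional[tuple[float, float]] = None,
) -> np.ndarray:
    """Piecewise-linear sharp transient, peak value exactly ``amp``.

    Rises 0 -> amp over ``rise_ms``, falls amp -> 0 over ``fall_ms``;
    optionally followed by a low-amplitude half-sine slow wave. Durations
    outside the 20-80 ms epileptiform definition warn but are allowed.
    """
    if rise_ms <= 0 or fall_ms <= 0:
        raise ValueError("rise_ms and fall_ms must be > 0")
    total = rise_ms + fall_ms
    if not 20 <= total <= 80:
        warnings.warn(
            f"template duration {total:.0f} ms is outside the 20-80 ms "
            "epileptiform spike definition",
            stacklevel=2,
        )
    n_rise = max(int(round(rise_ms * fs / 1000.0)), 1)
    n_fall = max(int(round(fall_ms * fs / 1000.0)), 1)
    rise = amp * np.arange(n_rise + 1) / n_rise
    fall = amp * (1.0 - np.arange(1, n_fall + 1) / n_fall)
    w = np.concatenate([rise, fall])
    if slow_wave is not None:
        sw_amp, sw_ms = slow_wave
        n_sw = max(int(round(sw_ms * fs / 1000.0)), 1)
        w = np.concatenate([w, sw_amp * np.sin(np.pi * np.arange(1, n_sw + 1) / n_sw)])
    return w


def _shaped_noise(rng: np.random.Generator, n: int, sd: float, fs: float) -> np.ndarray:
    """White Gaussian innovations low-pass shaped below 30 Hz (zero phase)."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    white = rng.normal(0.0, sd, size=n)
    if fs <= 2 * BASELINE_LOWPASS_HZ:
        return white
    b, a = sps.butter(4, BASELINE_LOWPASS_HZ, btype="low", fs=fs)
    return sps.filtfilt(b, a, white)


def _poisson_times(
    rng: np.random.Generator, spec: SynthSpec
) -> np.ndarray:
    """Poisson spike times thinned to the refractory gap, away from edges."""
    margin = spec.template_width_s
    lo, hi = margin, spec.duration - margin
    if hi <= lo:
        raise ValueError("duration too short for even one template")
    n = rng.poisson(spec.spike_rate * spec.duration)
    times = np.sort(rng.uniform(lo, hi, size=n))
    kept: list[float] = []
    for t in times:
        if not kept or t - kept[-1] >= spec.refractory_s:
            kept.append(float(t))
    return np.asarray(kept)


def _render(
    spec: SynthSpec,
    times: np.ndarray,
    amps: np.ndarray,
    noise: np.ndarray,
    label: str,
) -> Recording:
    """Sum of placed templates over the shaped baseline, as a Recording."""
    n = int(round(spec.duration * spec.fs))
    x = noise.copy() if noise.size else np.zeros(n)
    peak_off = max(int(round(spec.rise_ms * spec.fs / 1000.0)), 1)
    base = spike_template(spec.fs, spec.rise_ms, spec.fall_ms, 1.0, spec.slow_wave)
    for t, a in zip(times, amps):
        p = int(round(t * spec.fs))
        s = p - peak_off
        e = s + len(base)
        if s < 0 or e > n:  # pragma: no cover - placement margin prevents this
            continue
        x[s:e] += a * base
    meta = RecordingMetadata(
        experiment_name="synthetic",
        researcher="synth",
        animal_id="synthetic",
        group_id="sim",
        n_channels=1,
        fs=spec.fs,
        gain=1.0,
        filtered=False,
    )
    return Recording(metadata=meta, channel_labels=[label], data=x[np.newaxis, :])


def _jittered_amps(rng: np.random.Generator, spec: SynthSpec, k: int) -> np.ndarray:
    amps = spec.amp + rng.normal(0.0, spec.amp_jitter_sd, size=k)
    return np.maximum(amps, 0.1 * spec.amp)  # keep planted spikes detectable-signed


def simulate_channel(spec: SynthSpec) -> tuple[Recording, GroundTruth]:
    """One synthetic channel: shaped-noise baseline plus planted templates."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    times = _poisson_times(rng, spec)
    amps = _jittered_amps(rng, spec, len(times))
    noise = _shaped_noise(rng, n, spec.noise_sd, spec.fs)
    rec = _render(spec, times, amps, noise, "ref")
    truth = GroundTruth(
        true_times={"ref": list(times)},
        true_amps={"ref": list(amps)},
    )
    return rec, truth


def simulate_pair(spec: SynthSpec) -> tuple[Recording, Recording, GroundTruth]:
    """Reference channel plus a comparison channel with controlled coincidence.

    Each reference spike recurs on the comparison channel with probability
    ``coincidence_p`` at its time plus Gaussian jitter; independent
    comparison-only spikes are added at rate
    ``spike_rate * (1 - coincidence_p)``. Flags mark which reference spikes
    recurred (after refractory thinning on the comparison channel).
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    margin = spec.template_width_s

    ref_times = _poisson_times(rng, spec)
    ref_amps = _jittered_amps(rng, spec, len(ref_times))

    recur = rng.random(len(ref_times)) < spec.coincidence_p
    jitter = rng.normal(0.0, spec.time_jitter_sd, size=len(ref_times))

    # independent comparison-only spikes
    indep_spec = SynthSpec(**{**spec.to_dict(),
                              "spike_rate": spec.spike_rate * (1 - spec.coincidence_p)})
    n_indep = rng.poisson(indep_spec.spike_rate * spec.duration)
    indep_times = np.sort(rng.uniform(margin, spec.duration - margin, size=n_indep))

    # comparison train: coincident recurrences take precedence, then
    # independents that respect the refractory gap against everything kept
    flags = [False] * len(ref_times)
    comp_entries: list[tuple[float, int]] = []  # (time, ref index or -1)
    for i in np.flatnonzero(recur):
        t = ref_times[i] + jitter[i]
        if margin <= t <= spec.duration - margin:
            comp_entries.append((float(t), int(i)))
    comp_entries.sort()
    kept: list[tuple[float, int]] = []
    for t, i in comp_entries:
        if not kept or t - kept[-1][0] >= spec.refractory_s:
            kept.append((t, i))
    for t in indep_times:
        if all(abs(t - kt) >= spec.refractory_s for kt, _ in kept):
            kept.append((float(t), -1))
    kept.sort()
    for _, i in kept:
        if i >= 0:
            flags[i] = True
    comp_times = np.array([t for t, _ in kept])
    comp_amps = _jittered_amps(rng, spec, len(comp_times))

    ref_noise = _shaped_noise(rng, n, spec.noise_sd, spec.fs)
    comp_noise = _shaped_noise(rng, n, spec.noise_sd, spec.fs)
    ref_rec = _render(spec, ref_times, ref_amps, ref_noise, "ref")
    comp_rec = _render(spec, comp_times, comp_amps, comp_noise, "comp")
    truth = GroundTruth(
        true_times={"ref": list(ref_times), "comp": list(comp_times)},
        true_amps={"ref": list(ref_amps), "comp": list(comp_amps)},
        coincident_flags=flags,
    )
    return ref_rec, comp_rec, truth


def score_detection(
    true_times, detected_times, tol: float
) -> tuple[float, float, float]:
    """Precision, recall and F1 of a detection against planted spike times.

    Matching is one-to-one within ``tol`` seconds (same greedy-by-|Δt| rule
    as the coincidence analysis). Precision of an empty detection is NaN;
    recall of an empty truth is NaN; F1 is NaN whenever either is.
    """
    if not tol > 0:
        raise ValueError("tol must be > 0")
    true_times = np.sort(np.asarray(true_times, dtype=float))
    detected_times = np.sort(np.asarray(detected_times, dtype=float))
    matches = len(match_events(true_times, detected_times, tol))
    precision = matches / len(detected_times) if len(detected_times) else math.nan
    recall = matches / len(true_times) if len(true_times) else math.nan
    if math.isnan(precision) or math.isnan(recall):
        f1 = math.nan
    elif precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return precision, recall, f1
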