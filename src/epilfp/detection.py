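"""Automatic epileptiform spike detection with three thresholds.

Epileptiform spikes are transient sharp deflections (20-80 ms) standing
above the baseline, whose amplitude varies considerably across a recording
— unlike unit spikes, a single fixed threshold does not track them. The
detector therefore combines:

1. a *moving amplitude threshold*: within each one-second analysis window
   the threshold is a user-chosen percentage of the maximum amplitude
   observed in that window (60% of a 1 mV window maximum -> 0.6 mV);
2. a *fixed amplitude floor* guaranteeing a minimum acceptable spike
   amplitude, so quiet windows do not admit baseline noise;
3. a *temporal (refractory) threshold*: a minimum allowed distance between
   consecutive accepted spikes, so polyphasic complexes count once.

Detection reports the events plus the summary statistics used in practice:
spike count, max/mean/min amplitude, max/mean/min inter-spike interval, and
firing rate over the analyzed span.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

from .io import Recording

__all__ = [
    "DetectionParams",
    "SpikeEvent",
    "DetectionSummary",
    "DetectionResult",
    "moving_thresholds",
    "detect_spikes",
    "summarize",
]


def _rectify(x: np.ndarray, polarity: str) -> np.ndarray:
    """Amplitude relative to baseline for the chosen polarity."""
    if polarity == "both":
        return np.abs(x)
    if polarity == "positive":
        return np.asarray(x, dtype=float)
    if polarity == "negative":
        return -np.asarray(x, dtype=float)
    raise ValueError(f"polarity must be 'positive', 'negative' or 'both', got {polarity!r}")


@dataclass
class DetectionParams:
    """User inputs of the three-threshold detector.

    percent
        Moving-threshold percentage in [0, 100] of each window's maximum
        amplitude.
    fixed_thr
        Minimum acceptable spike amplitude in mV (>= 0).
    min_dist
        Minimum allowed distance between consecutive spikes, seconds (> 0).
    win_len
        Analysis-window length in seconds (default 1.0).
    polarity
        ``"both"`` detects on the rectified signal (default; LFP spikes may
        be negative-going), ``"positive"``/``"negative"`` on one side only.
    t_start, t_end
        Analyzed span in seconds, half-open ``[t_start, t_end)``; ``t_end``
        of ``None`` means the end of the recording.
    """

    percent: float = 40.0
    fixed_thr: float = 0.1
    min_dist: float = 0.1
    win_len: float = 1.0
    polarity: str = "both"
    t_start: float = 0.0
    t_end: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0 <= self.percent <= 100:
            raise ValueError("percent must be in [0, 100]")
        if self.fixed_thr < 0:
            raise ValueError("fixed_thr must be >= 0")
        if not self.min_dist > 0:
            raise ValueError("min_dist must be > 0")
        if not self.win_len > 0:
            raise ValueError("win_len must be > 0")
        if self.t_end is not None and not self.t_start < self.t_end:
            raise ValueError("t_start must be < t_end")
        _rectify(np.zeros(1), self.polarity)  # validate

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DetectionParams":
        return cls(**d)


@dataclass
class SpikeEvent:
    """One detected spike: peak time (s), amplitude magnitude at the peak
    (mV), absolute sample index, and the analysis window that admitted it."""

    time: float
    amplitude: float
    sample_index: int
    window_index: int

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SpikeEvent":
        return cls(**d)


@dataclass
class DetectionSummary:
    """Spike-train statistics over the analyzed span.

    Undefined statistics (no events for amplitudes, fewer than two for
    inter-spike intervals) are NaN, never 0.
    """

    n_spikes: int
    amp_max: float
    amp_mean: float
    amp_min: float
    isi_max: float
    isi_mean: float
    isi_min: float
    firing_rate: float

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DetectionSummary":
        d = {k: (math.nan if v is None else v) for k, v in d.items()}
        return cls(**d)


@dataclass
class DetectionResult:
    """Events (time-sorted), the parameters that produced them, summary
    statistics, and the per-window moving thresholds actually applied."""

    events: list[SpikeEvent]
    params: DetectionParams
    summary: DetectionSummary
    thresholds: np.ndarray
    channel: str = ""

    analysis_type = "detection"

    @property
    def times(self) -> np.ndarray:
        return np.array([e.time for e in self.events])

    def to_dict(self) -> dict:
        return {
            "channel": self.channel,
            "params": self.params.to_dict(),
            "results": {
                "events": [e.to_dict() for e in self.events],
                "summary": self.summary.to_dict(),
                "thresholds_mV": np.asarray(self.thresholds).tolist(),
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DetectionResult":
        res = d["results"]
        return cls(
            events=[SpikeEvent.from_dict(e) for e in res["events"]],
            params=DetectionParams.from_dict(d["params"]),
            summary=DetectionSummary.from_dict(res["summary"]),
            thresholds=np.asarray(res["thresholds_mV"], dtype=float),
            channel=d.get("channel", ""),
        )


def moving_thresholds(
    signal,
    fs: float,
    percent: float,
    win_len: float = 1.0,
    polarity: str = "both",
) -> np.ndarray:
    """Per-window moving amplitude thresholds in mV.

    The signal is partitioned into contiguous non-overlapping windows of
    ``win_len`` seconds (the final window may be shorter); the threshold of
    window *w* is ``percent/100`` times the maximum rectified amplitude
    observed in *w*. With percent=60 and a window maximum of 1 mV the
    threshold for that window is 0.6 mV.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0:
        raise ValueError("empty signal")
    if not fs > 0:
        raise ValueError("fs must be > 0")
    if not 0 <= percent <= 100:
        raise ValueError("percent must be in [0, 100]")
    rect = _rectify(signal, polarity)
    wlen = max(int(round(win_len * fs)), 1)
    n_win = int(np.ceil(len(rect) / wlen))
    return np.array(
        [percent / 100.0 * rect[w * wlen:(w + 1) * wlen].max() for w in range(n_win)]
    )


def _candidate_events(
    rect: np.ndarray, eff_thr: np.ndarray, offset: int, fs: float, wlen: int
) -> list[SpikeEvent]:
    """Maximal suprathreshold runs, each reduced to its extremum sample.

    A run crossing a window boundary stays one run (thresholds are applied
    per sample); the window index recorded is the one containing the
    extremum.
    """
    mask = rect >= eff_thr
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)  # exclusive
    events = []
    for s, e in zip(starts, stops):
        k = s + int(np.argmax(rect[s:e]))
        events.append(
            SpikeEvent(
                time=(offset + k) / fs,
                amplitude=float(rect[k]),
                sample_index=offset + k,
                window_index=k // wlen,
            )
        )
    return events


def _enforce_min_dist(events: list[SpikeEvent], min_dist: float) -> list[SpikeEvent]:
    """Greedy refractory selection: descending amplitude, ties earlier time.

    A candidate is kept iff no already-kept spike lies within ``min_dist``
    of it, so a polyphasic complex is counted once at its dominant
    deflection.
    """
    order = sorted(events, key=lambda ev: (-ev.amplitude, ev.time))
    kept_times: list[float] = []
    kept: list[SpikeEvent] = []
    for ev in order:
        i = bisect.bisect_left(kept_times, ev.time)
        if i > 0 and ev.time - kept_times[i - 1] < min_dist:
            continue
        if i < len(kept_times) and kept_times[i] - ev.time < min_dist:
            continue
        kept_times.insert(i, ev.time)
        kept.append(ev)
    return sorted(kept, key=lambda ev: ev.time)


def detect_spikes(
    recording: Recording, channel: str, params: DetectionParams
) -> DetectionResult:
    """Run the three-threshold detector on one channel.

    Per-sample effective threshold is the maximum of the window's moving
    threshold and the fixed floor; candidate events are maximal
    suprathreshold runs reduced to their extremum; the temporal threshold
    is enforced greedily in descending amplitude order. Windows are
    anchored at ``t_start``.
    """
    x = recording.channel(channel)
    fs = recording.metadata.fs
    t_end = params.t_end if params.t_end is not None else recording.duration
    if t_end > recording.duration + 0.5 / fs:
        raise ValueError(
            f"t_end={t_end} s exceeds recording duration {recording.duration} s"
        )
    if params.t_start < 0:
        raise ValueError("t_start must be >= 0")
    i0 = int(round(params.t_start * fs))
    i1 = min(int(round(t_end * fs)), len(x))
    seg = x[i0:i1]
    thresholds = moving_thresholds(
        seg, fs, params.percent, params.win_len, params.polarity
    )
    wlen = max(int(round(params.win_len * fs)), 1)
    per_sample = np.maximum(
        np.repeat(thresholds, wlen)[: len(seg)], params.fixed_thr
    )
    rect = _rectify(seg, params.polarity)
    candidates = _candidate_events(rect, per_sample, i0, fs, wlen)
    events = _enforce_min_dist(candidates, params.min_dist)
    summary = summarize(events, params.t_start, t_end, params.min_dist)
    return DetectionResult(
        events=events,
        params=params,
        summary=summary,
        thresholds=thresholds,
        channel=channel,
    )


def summarize(
    events: list[SpikeEvent], t_start: float, t_end: float, min_dist: float = 0.0
) -> DetectionSummary:
    """Amplitude/ISI statistics and firing rate for a time-sorted event list.

    Firing rate is spikes per second over ``t_end - t_start``. With fewer
    than two events the ISI statistics are NaN; with none, the amplitude
    statistics are NaN too and the rate is 0.
    """
    if not t_end > t_start:
        raise ValueError("t_end must be > t_start")
    n = len(events)
    span = t_end - t_start
    if n == 0:
        nan = math.nan
        return DetectionSummary(0, nan, nan, nan, nan, nan, nan, 0.0)
    amps = np.array([e.amplitude for e in events])
    times = np.array([e.time for e in events])
    if n >= 2:
        isis = np.diff(times)
        isi_max, isi_mean, isi_min = isis.max(), isis.mean(), isis.min()
    else:
        isi_max = isi_mean = isi_min = math.nan
    return DetectionSummary(
        n_spikes=n,
        amp_max=float(amps.max()),
        amp_mean=float(amps.mean()),
        amp_min=float(amps.min()),
        isi_max=float(isi_max),
        isi_mean=float(isi_mean),
        isi_min=float(isi_min),
        firing_rate=n / span,
    )
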