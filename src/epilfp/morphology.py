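"""Average-spike morphology: representative waveform and slope metrics.

Epochs around detected spike peaks are extracted from the raw signal,
aligned on the peak sample, and averaged into the representative
epileptiform spike. From that average three slope metrics are computed:
the rising segment (onset to peak), the descent segment (peak to descent
end) and the overall spike (mean absolute instantaneous slope over the
onset-to-end support). The default epoch half-extent of 40 ms covers the
80 ms upper bound of the epileptiform-spike duration definition; the
trailing slow wave is deliberately outside it.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

from .detection import DetectionResult
from .io import Recording

__all__ = [
    "MorphologyParams",
    "MorphologyResult",
    "extract_epochs",
    "average_spike",
    "slope_metrics",
    "analyze_morphology",
]

#: hysteresis for landmark search, as a fraction of peak-to-trough range;
#: 0 recovers the strict nearest-local-minimum rule
LANDMARK_REL_TOL = 0.02


class CoverageError(ValueError):
    """No spike epoch fits inside the signal."""


class MorphologyError(ValueError):
    """Waveform has no identifiable central peak."""


@dataclass
class MorphologyParams:
    """half_width: epoch half-extent around each spike peak, seconds
    (default 0.04 s, consistent with the 20-80 ms spike duration)."""

    half_width: float = 0.04

    def __post_init__(self) -> None:
        if not self.half_width > 0:
            raise ValueError("half_width must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "MorphologyParams":
        return cls(**d)


@dataclass
class MorphologyResult:
    """Averaged spike waveform and its three slope metrics.

    Slopes are in mV/s; ``descent_slope`` is negative for a falling
    segment. ``onset_offset``/``end_offset`` are the rising-onset and
    descent-end times relative to the peak (<= 0 and >= 0 respectively).
    """

    avg_waveform: np.ndarray
    fs: float
    n_epochs: int
    n_dropped: int
    rising_slope: float
    descent_slope: float
    overall_slope: float
    onset_offset: float
    end_offset: float
    params: MorphologyParams = None
    channel: str = ""

    analysis_type = "morphology"

    def __post_init__(self) -> None:
        if self.params is None:
            self.params = MorphologyParams()
        self.avg_waveform = np.asarray(self.avg_waveform, dtype=float)

    def to_dict(self) -> dict:
        return {
            "channel": self.channel,
            "params": self.params.to_dict(),
            "results": {
                "avg_waveform_mV": self.avg_waveform.tolist(),
                "fs": self.fs,
                "n_epochs": self.n_epochs,
                "n_dropped": self.n_dropped,
                "rising_slope_mV_s": self.rising_slope,
                "descent_slope_mV_s": self.descent_slope,
                "overall_slope_mV_s": self.overall_slope,
                "onset_offset_s": self.onset_offset,
                "end_offset_s": self.end_offset,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MorphologyResult":
        r = d["results"]
        return cls(
            avg_waveform=np.asarray(r["avg_waveform_mV"], dtype=float),
            fs=r["fs"],
            n_epochs=r["n_epochs"],
            n_dropped=r["n_dropped"],
            rising_slope=r["rising_slope_mV_s"],
            descent_slope=r["descent_slope_mV_s"],
            overall_slope=r["overall_slope_mV_s"],
            onset_offset=r["onset_offset_s"],
            end_offset=r["end_offset_s"],
            params=MorphologyParams.from_dict(d["params"]),
            channel=d.get("channel", ""),
        )


def extract_epochs(
    signal, fs: float, spike_times, half_width: float = 0.04
) -> tuple[np.ndarray, int]:
    """Peak-aligned epochs around each spike time.

    Returns ``(epochs, n_dropped)`` where ``epochs`` is an
    ``n_epochs x (2*round(half_width*fs)+1)`` matrix; spikes whose full
    window does not fit inside the signal are dropped and counted.
    """
    signal = np.asarray(signal, dtype=float)
    spike_times = np.asarray(spike_times, dtype=float)
    if spike_times.size == 0:
        raise CoverageError("no spike times supplied")
    hw = int(round(half_width * fs))
    rows, dropped = [], 0
    for t in spike_times:
        p = int(round(t * fs))
        if p - hw < 0 or p + hw >= len(signal):
            dropped += 1
            continue
        rows.append(signal[p - hw:p + hw + 1])
    if not rows:
        raise CoverageError(
            f"none of the {len(spike_times)} spikes yields a complete "
            f"{2 * hw + 1}-sample window"
        )
    return np.vstack(rows), dropped


def average_spike(epochs) -> np.ndarray:
    """Pointwise mean across epochs — the representative average spike."""
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    if epochs.size == 0:
        raise CoverageError("empty epoch matrix")
    return epochs.mean(axis=0)


def _walk_landmark(w: np.ndarray, center: int, direction: int, tol: float) -> int:
    """Nearest flanking local minimum, with hysteresis ``tol``.

    Walk away from the peak while the waveform keeps descending by more
    than ``tol`` per step; stop at the first stall (a local minimum up to
    tolerance) or at the window edge.
    """
    i = center
    stop = len(w) - 1 if direction > 0 else 0
    while i != stop and w[i + direction] < w[i] - tol:
        i += direction
    return i


def slope_metrics(
    avg_waveform,
    fs: float,
    rel_tol: float = LANDMARK_REL_TOL,
    params: Optional[MorphologyParams] = None,
    n_epochs: int = 1,
    n_dropped: int = 0,
    channel: str = "",
) -> MorphologyResult:
    """Slope metrics of a peak-centered average spike waveform.

    The rising onset is the nearest local minimum before the central peak
    (window start if none) and the descent end the nearest local minimum
    after it (window end if none); the landmark search tolerates
    sub-``rel_tol`` wiggles so residual averaged noise on a flat baseline
    does not truncate the segments. Then::

        rising_slope  = (v_peak - v_onset) / (t_peak - t_onset)
        descent_slope = (v_end  - v_peak)  / (t_end  - t_peak)
        overall_slope = mean over [onset, end] of |dv| * fs

    Raises :class:`MorphologyError` if the waveform is flat or its center
    is not a local maximum.
    """
    w = np.asarray(avg_waveform, dtype=float)
    if w.ndim != 1 or len(w) < 3:
        raise MorphologyError("waveform must be a 1-D series of >= 3 samples")
    c = len(w) // 2
    rng = w.max() - w.min()
    if rng == 0:
        raise MorphologyError("flat waveform: no identifiable peak")
    if not (w[c] >= w[c - 1] and w[c] >= w[c + 1] and w[c] > w.min()):
        raise MorphologyError("central sample is not a peak above its surroundings")
    tol = rel_tol * rng
    i_on = _walk_landmark(w, c, -1, tol)
    i_end = _walk_landmark(w, c, +1, tol)
    if i_on == c or i_end == c:
        raise MorphologyError("peak has no rising or falling flank")
    rising = (w[c] - w[i_on]) / ((c - i_on) / fs)
    descent = (w[i_end] - w[c]) / ((i_end - c) / fs)
    overall = float(np.mean(np.abs(np.diff(w[i_on:i_end + 1]))) * fs)
    return MorphologyResult(
        avg_waveform=w,
        fs=fs,
        n_epochs=n_epochs,
        n_dropped=n_dropped,
        rising_slope=float(rising),
        descent_slope=float(descent),
        overall_slope=overall,
        onset_offset=(i_on - c) / fs,
        end_offset=(i_end - c) / fs,
        params=params if params is not None else MorphologyParams(),
        channel=channel,
    )


def analyze_morphology(
    recording: Recording,
    channel: str,
    detection: DetectionResult,
    params: Optional[MorphologyParams] = None,
) -> MorphologyResult:
    """Full morphology pass: epochs -> average spike -> slope metrics."""
    params = params if params is not None else MorphologyParams()
    x = recording.channel(channel)
    epochs, dropped = extract_epochs(
        x, recording.metadata.fs, detection.times, params.half_width
    )
    avg = average_spike(epochs)
    # detection reports rectified amplitudes; align polarity so the
    # averaged peak is a maximum before measuring slopes
    c = len(avg) // 2
    if avg[c] < 0 and abs(avg[c]) >= avg.max():
        avg = -avg
    return slope_metrics(
        avg,
        recording.metadata.fs,
        params=params,
        n_epochs=epochs.shape[0],
        n_dropped=dropped,
        channel=channel,
    )
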