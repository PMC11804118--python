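"""Zero-phase FIR/IIR bandpass filtering for LFP recordings.

Slow drifts and high-frequency content both hurt amplitude-threshold spike
detection, so recordings are band-limited to 10-100 Hz by default. Two
designs are offered: a linear-phase FIR (least-squares approximation of the
ideal bandpass, smoothed by a Hann window) and a Butterworth IIR. Either is
applied with zero phase: filter forward, reverse the sequence, filter
again, reverse back. The two passes square the magnitude response and
cancel the phase response, so spike peaks are not displaced in time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps

__all__ = ["FilterSpec", "design_bandpass", "apply_zero_phase", "bandpass_filter"]

#: half-width of the FIR least-squares transition bands, Hz
FIR_TRANSITION_HZ = 5.0
DEFAULT_LOW_HZ = 10.0
DEFAULT_HIGH_HZ = 100.0
DEFAULT_IIR_ORDER = 4


@dataclass
class FilterSpec:
    """A self-contained bandpass filter design.

    ``b``/``a`` are the transfer-function coefficients (``a == [1.0]`` for
    FIR); the spec can be re-applied to any signal sampled at ``fs``.
    """

    kind: str               # "fir" | "iir"
    low: float              # lower passband edge, Hz
    high: float             # upper passband edge, Hz
    fs: float
    numtaps: Optional[int] = None   # fir only, odd
    order: Optional[int] = None     # iir only, per pass
    b: np.ndarray = field(default_factory=lambda: np.array([1.0]))
    a: np.ndarray = field(default_factory=lambda: np.array([1.0]))

    def __post_init__(self) -> None:
        if self.kind not in ("fir", "iir"):
            raise ValueError(f"kind must be 'fir' or 'iir', got {self.kind!r}")
        _check_band(self.low, self.high, self.fs)
        if self.kind == "fir" and self.numtaps is not None and self.numtaps % 2 == 0:
            raise ValueError("FIR numtaps must be odd (symmetric linear-phase design)")

    @property
    def pad_len(self) -> int:
        """Reflection-padding length used by zero-phase application."""
        return 3 * (self.numtaps if self.kind == "fir" else 3 * self.order)

    def is_stable(self) -> bool:
        """All poles strictly inside the unit circle (always true for FIR)."""
        if len(self.a) == 1:
            return True
        return bool(np.all(np.abs(np.roots(self.a)) < 1.0))

    def response(self, freqs_hz) -> np.ndarray:
        """Single-pass magnitude response |H(f)| at the given frequencies."""
        _, h = sps.freqz(self.b, self.a, worN=np.atleast_1d(freqs_hz), fs=self.fs)
        return np.abs(h)


def _check_band(low: float, high: float, fs: float) -> None:
    if fs <= 2 * high:
        raise ValueError(
            f"fs={fs} Hz violates Nyquist for high edge {high} Hz (need fs > 2*high)"
        )
    if not (0 < low < high < fs / 2):
        raise ValueError(
            f"band edges must satisfy 0 < low < high < fs/2; got low={low}, "
            f"high={high}, fs={fs}"
        )


def default_numtaps(fs: float) -> int:
    """Smallest odd integer >= fs — a one-second impulse response.

    A long filter is needed for a credible 10 Hz lower edge.
    """
    n = int(np.ceil(fs))
    return n if n % 2 == 1 else n + 1


def design_bandpass(
    kind: str,
    fs: float,
    low: float = DEFAULT_LOW_HZ,
    high: float = DEFAULT_HIGH_HZ,
    order_or_taps: Optional[int] = None,
) -> FilterSpec:
    """Design a bandpass filter for LFP preprocessing.

    FIR: least-squares approximation of the ideal bandpass (transition
    bands +/-5 Hz around each edge), multiplied pointwise by a Hann window
    to smooth the response. Default length is a one-second impulse
    response (smallest odd integer >= fs). IIR: Butterworth of the given
    order (default 4) per pass.
    """
    _check_band(low, high, fs)
    if kind == "fir":
        numtaps = default_numtaps(fs) if order_or_taps is None else int(order_or_taps)
        if numtaps % 2 == 0:
            raise ValueError("FIR numtaps must be odd")
        lo_stop = max(low - FIR_TRANSITION_HZ, 0.0)
        hi_stop = min(high + FIR_TRANSITION_HZ, fs / 2)
        bands = [0.0, lo_stop, low, high, hi_stop, fs / 2]
        desired = [0.0, 0.0, 1.0, 1.0, 0.0, 0.0]
        b = sps.firls(numtaps, bands, desired, fs=fs)
        b = b * sps.windows.hann(numtaps, sym=True)
        return FilterSpec(kind="fir", low=low, high=high, fs=fs, numtaps=numtaps, b=b)
    if kind == "iir":
        order = DEFAULT_IIR_ORDER if order_or_taps is None else int(order_or_taps)
        if order < 1:
            raise ValueError("IIR order must be a positive integer")
        b, a = sps.butter(order, [low, high], btype="bandpass", fs=fs)
        spec = FilterSpec(
            kind="iir", low=low, high=high, fs=fs, order=order,
            b=np.asarray(b), a=np.asarray(a),
        )
        if not spec.is_stable():  # pragma: no cover - butter designs are stable
            raise ValueError("designed IIR filter is unstable")
        return spec
    raise ValueError(f"kind must be 'fir' or 'iir', got {kind!r}")


def apply_zero_phase(x, spec: FilterSpec) -> np.ndarray:
    """Filter with zero phase: forward, reverse, forward again, reverse back.

    Edge transients are mitigated by odd-reflection padding of
    ``spec.pad_len`` samples on each side, trimmed after filtering. Output
    length equals input length; the effective magnitude response is the
    single-pass response squared and the phase response is zero, so a
    symmetric pulse keeps its extremum sample.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("apply_zero_phase expects a 1-D voltage series")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    pad = spec.pad_len
    if len(x) <= pad:
        raise ValueError(
            f"signal of {len(x)} samples is too short for stable zero-phase "
            f"application (needs > {pad})"
        )
    # odd reflection about the end samples keeps the extension continuous
    left = 2 * x[0] - x[pad:0:-1]
    right = 2 * x[-1] - x[-2:-pad - 2:-1]
    ext = np.concatenate([left, x, right])
    # seed each pass with the filter's step-response steady state scaled to
    # the first sample, so the remaining startup transient stays inside the
    # padding even for narrow-band IIR designs
    zi = sps.lfilter_zi(spec.b, spec.a)
    y, _ = sps.lfilter(spec.b, spec.a, ext, zi=zi * ext[0])
    y = y[::-1]
    y, _ = sps.lfilter(spec.b, spec.a, y, zi=zi * y[0])
    y = y[::-1]
    return y[pad:pad + len(x)]


def bandpass_filter(
    x,
    fs: float,
    kind: str = "fir",
    low: float = DEFAULT_LOW_HZ,
    high: float = DEFAULT_HIGH_HZ,
    order_or_taps: Optional[int] = None,
) -> np.ndarray:
    """Design-and-apply convenience for one signal.

    For FIR the default one-second length is capped at ``len(x) // 4``
    (made odd, with a warning) so short signals remain filterable.
    """
    x = np.asarray(x, dtype=float)
    if kind == "fir" and order_or_taps is None:
        numtaps = default_numtaps(fs)
        cap = len(x) // 4
        if numtaps > cap:
            numtaps = cap if cap % 2 == 1 else cap - 1
            if numtaps < 3:
                raise ValueError("signal too short to design a usable FIR filter")
            warnings.warn(
                f"FIR length capped at {numtaps} taps (signal has {len(x)} samples)",
                stacklevel=2,
            )
        order_or_taps = numtaps
    spec = design_bandpass(kind, fs, low=low, high=high, order_or_taps=order_or_taps)
    return apply_zero_phase(x, spec)
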