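"""Pearson correlation between channels of a recording.

For two equal-length series A and B with means â, b̂ and sample standard
deviations σ_A, σ_B,

    r = Σ (a_i − â)(b_i − b̂) / ((n − 1) σ_A σ_B)

ranges from −1 (inverse) through 0 (no linear interdependence) to 1
(direct correlation). The matrix form generalizes the two-substrate
comparison to all channel pairs over a chosen span; undefined entries
(zero variance) are NaN, never silently 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io import Recording

__all__ = [
    "PearsonComponents",
    "CorrelationResult",
    "pearson",
    "correlation_matrix",
    "plot_correlation",
]


class UndefinedCorrelationError(ValueError):
    """Zero variance in one of the series: r is undefined."""


@dataclass
class PearsonComponents:
    """The Pearson coefficient together with the means and sample standard
    deviations that define it."""

    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    r: float
    n: int


def pearson(a, b) -> PearsonComponents:
    """Pearson correlation of two voltage series (sample normalization)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.ndim != 1 or a.size < 2:
        raise ValueError("inputs must be 1-D series of length >= 2")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("inputs must be finite")
    n = a.size
    ma, mb = a.mean(), b.mean()
    ac, bc = a - ma, b - mb
    saa, sbb = np.dot(ac, ac), np.dot(bc, bc)
    sa = float(np.sqrt(saa / (n - 1)))
    sb = float(np.sqrt(sbb / (n - 1)))
    if sa == 0 or sb == 0:
        raise UndefinedCorrelationError(
            "zero variance in at least one series; correlation undefined"
        )
    # (n-1)*sd_a*sd_b == sqrt(saa*sbb); the product form keeps r(x, +/-x)
    # exactly +/-1 under floating point
    r = float(np.dot(ac, bc) / np.sqrt(saa * sbb))
    r = min(1.0, max(-1.0, r))  # clamp float round-off at the extremes
    return PearsonComponents(
        mean_a=float(ma), mean_b=float(mb), sd_a=float(sa), sd_b=float(sb),
        r=r, n=int(n),
    )


@dataclass
class CorrelationResult:
    """Channel-by-channel Pearson coefficient matrix over a span.

    ``matrix`` is symmetric with unit diagonal; entries whose correlation
    is undefined (a constant channel) are NaN.
    """

    matrix: np.ndarray
    channel_labels: list[str]
    t_start: float
    t_end: float

    analysis_type = "correlation"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)

    def to_dict(self) -> dict:
        return {
            "params": {"t_start": self.t_start, "t_end": self.t_end},
            "results": {
                "channel_labels": list(self.channel_labels),
                "matrix": self.matrix.tolist(),
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CorrelationResult":
        r = d["results"]
        m = np.array(
            [[np.nan if v is None else v for v in row] for row in r["matrix"]],
            dtype=float,
        )
        return cls(
            matrix=m,
            channel_labels=list(r["channel_labels"]),
            t_start=d["params"]["t_start"],
            t_end=d["params"]["t_end"],
        )


def correlation_matrix(
    recording: Recording, t_start: float = 0.0, t_end: Optional[float] = None
) -> CorrelationResult:
    """Pearson coefficient matrix across all channel pairs in a span."""
    fs = recording.metadata.fs
    if t_end is None:
        t_end = recording.duration
    if t_start < 0 or t_end > recording.duration + 0.5 / fs or t_start >= t_end:
        raise ValueError(
            f"span [{t_start}, {t_end}) outside recording of "
            f"{recording.duration} s"
        )
    i0, i1 = int(round(t_start * fs)), min(int(round(t_end * fs)), recording.n_samples)
    seg = recording.data[:, i0:i1]
    k = seg.shape[0]
    m = np.full((k, k), np.nan)
    defined = seg.std(axis=1, ddof=1) > 0
    for i in range(k):
        if defined[i]:
            m[i, i] = 1.0
        for j in range(i + 1, k):
            if defined[i] and defined[j]:
                m[i, j] = m[j, i] = pearson(seg[i], seg[j]).r
    return CorrelationResult(
        matrix=m,
        channel_labels=list(recording.channel_labels),
        t_start=float(t_start),
        t_end=float(t_end),
    )


def plot_correlation(result: CorrelationResult, path) -> None:
    """Save the coefficient matrix as a heat map PNG (side effect only)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    k = len(result.channel_labels)
    fig, ax = plt.subplots(figsize=(1.2 * k + 2, 1.2 * k + 1.5))
    im = ax.imshow(result.matrix, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(k), result.channel_labels, rotation=45, ha="right")
    ax.set_yticks(range(k), result.channel_labels)
    for i in range(k):
        for j in range(k):
            v = result.matrix[i, j]
            ax.text(j, i, "n/a" if np.isnan(v) else f"{v:.2f}",
                    ha="center", va="center", fontsize=9)
    fig.colorbar(im, ax=ax, label="Pearson r")
    ax.set_title(f"Channel correlation, {result.t_start:g}-{result.t_end:g} s")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
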