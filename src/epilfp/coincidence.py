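"""Ictal spike coincidence between two channels.

One channel is designated the reference and the other the comparison
channel; a reference spike is coincident if a comparison spike falls
within the coincidence window of it. Matching is one-to-one and greedy by
ascending time offset, so a dense comparison train cannot certify one
reference spike twice. The headline number is the percentage of matched
reference spikes; the matched count per analyzed second is reported
alongside, since "percentage over the analyzed period" admits either
normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np

from .detection import DetectionResult

__all__ = ["CoincidenceParams", "CoincidenceResult", "match_events", "coincidence"]


class UndefinedPercentageError(ValueError):
    """No reference spikes in the analyzed span: percent is undefined."""


@dataclass
class CoincidenceParams:
    """window: maximum |Δt| in seconds for two spikes to count as the same
    synchronous event; t_start/t_end bound the analyzed span."""

    window: float = 0.1
    t_start: float = 0.0
    t_end: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.window > 0:
            raise ValueError("window must be > 0")
        if self.t_end is not None and not self.t_start < self.t_end:
            raise ValueError("t_start must be < t_end")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CoincidenceParams":
        return cls(**d)


@dataclass
class CoincidenceResult:
    """Matched reference/comparison spike pairs and the percent coincidence."""

    n_ref: int
    n_comp: int
    n_matched: int
    percent: float
    matched_per_s: float        # alternative time normalization
    pairs: list[tuple[float, float]]
    params: CoincidenceParams = None
    ref_channel: str = ""
    comp_channel: str = ""

    analysis_type = "coincidence"

    def __post_init__(self) -> None:
        if self.params is None:
            self.params = CoincidenceParams()
        self.pairs = [tuple(p) for p in self.pairs]

    def to_dict(self) -> dict:
        return {
            "ref_channel": self.ref_channel,
            "comp_channel": self.comp_channel,
            "params": self.params.to_dict(),
            "results": {
                "n_ref": self.n_ref,
                "n_comp": self.n_comp,
                "n_matched": self.n_matched,
                "percent": self.percent,
                "matched_per_s": self.matched_per_s,
                "pairs": [list(p) for p in self.pairs],
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CoincidenceResult":
        r = d["results"]
        return cls(
            n_ref=r["n_ref"],
            n_comp=r["n_comp"],
            n_matched=r["n_matched"],
            percent=r["percent"],
            matched_per_s=r["matched_per_s"],
            pairs=[tuple(p) for p in r["pairs"]],
            params=CoincidenceParams.from_dict(d["params"]),
            ref_channel=d.get("ref_channel", ""),
            comp_channel=d.get("comp_channel", ""),
        )


def match_events(
    ref_times: Sequence[float], comp_times: Sequence[float], window: float
) -> list[tuple[float, float]]:
    """One-to-one greedy matching of two sorted spike trains.

    Candidate pairs with ``|Δt| <= window`` are admitted in ascending
    ``|Δt|`` order (ties: earlier reference time, then earlier comparison
    time); a pair is kept iff neither member is already matched. Returns
    ``(ref_time, comp_time)`` pairs sorted by reference time.
    """
    ref = np.asarray(ref_times, dtype=float)
    comp = np.asarray(comp_times, dtype=float)
    if ref.size == 0 or comp.size == 0:
        return []
    cands = []
    lo = np.searchsorted(comp, ref - window, side="left")
    hi = np.searchsorted(comp, ref + window, side="right")
    for i, (a, b) in enumerate(zip(lo, hi)):
        for j in range(a, b):
            cands.append((abs(ref[i] - comp[j]), ref[i], comp[j], i, j))
    cands.sort()
    ref_used = np.zeros(ref.size, dtype=bool)
    comp_used = np.zeros(comp.size, dtype=bool)
    pairs = []
    for _, rt, ct, i, j in cands:
        if not ref_used[i] and not comp_used[j]:
            ref_used[i] = comp_used[j] = True
            pairs.append((rt, ct))
    pairs.sort()
    return pairs


def coincidence(
    ref: DetectionResult, comp: DetectionResult, params: Optional[CoincidenceParams] = None
) -> CoincidenceResult:
    """Coincidence between reference and comparison detection results.

    Events are filtered to ``[t_start, t_end)``, matched with
    :func:`match_events`, and summarized as
    ``percent = 100 * n_matched / n_ref``. A span with no reference spikes
    raises :class:`UndefinedPercentageError` — 0 matches of 0 spikes is not
    0 % coincidence.
    """
    params = params if params is not None else CoincidenceParams()
    t0 = params.t_start
    t1 = params.t_end
    if t1 is None:
        t1 = max(
            [t0] + [e.time for e in ref.events] + [e.time for e in comp.events]
        ) + 1e-9
    ref_t = np.array([e.time for e in ref.events if t0 <= e.time < t1])
    comp_t = np.array([e.time for e in comp.events if t0 <= e.time < t1])
    if ref_t.size == 0:
        raise UndefinedPercentageError(
            "no reference spikes in the analyzed span; percent coincidence "
            "is undefined"
        )
    pairs = match_events(ref_t, comp_t, params.window)
    n_matched = len(pairs)
    return CoincidenceResult(
        n_ref=int(ref_t.size),
        n_comp=int(comp_t.size),
        n_matched=n_matched,
        percent=100.0 * n_matched / ref_t.size,
        matched_per_s=n_matched / (t1 - t0),
        pairs=pairs,
        params=CoincidenceParams(window=params.window, t_start=t0, t_end=float(t1)),
        ref_channel=ref.channel,
        comp_channel=comp.channel,
    )
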