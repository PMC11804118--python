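"""Shared fixtures: synthetic recordings and a minimal EDF writer.

All fixture data is generated programmatically; nothing binary ships with
the test suite.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import epilfp

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture
def meta() -> epilfp.RecordingMetadata:
    return epilfp.RecordingMetadata(
        experiment_name="exp1",
        researcher="tester",
        animal_id="R01",
        group_id="control",
        n_channels=2,
        fs=1000.0,
        gain=1.0,
    )


@pytest.fixture
def clean_recording(meta) -> epilfp.Recording:
    """Two noise-free sinusoid channels, 2 s at 1 kHz."""
    t = np.arange(2000) / 1000.0
    data = np.vstack([np.sin(2 * np.pi * 5 * t), np.cos(2 * np.pi * 5 * t)])
    return epilfp.Recording(metadata=meta, channel_labels=["ctx", "hpc"], data=data)


@pytest.fixture
def spiky_recording():
    """Synthetic single-channel recording with planted spikes + truth."""
    spec = epilfp.SynthSpec(duration=30.0, seed=11)
    return epilfp.simulate_channel(spec)


def write_minimal_edf(path, data_mv: np.ndarray, fs: float, labels) -> None:
    """Write a minimal valid EDF file (synthetic, for reader tests only).

    One-second data records, 16-bit samples, physical range +/-10 mV.
    """
    ns = len(labels)
    spr = int(fs)
    n_rec = data_mv.shape[1] // spr
    pmin, pmax = -10.0, 10.0
    dmin, dmax = -32768, 32767

    def field(vals, width):
        return "".join(str(v).ljust(width) for v in vals).encode()

    hdr = b"0       "
    hdr += b"X patient".ljust(80) + b"X recording".ljust(80)
    hdr += b"01.01.20" + b"00.00.00"
    hdr += str(256 * (ns + 1)).ljust(8).encode()
    hdr += b" " * 44
    hdr += str(n_rec).ljust(8).encode() + b"1       "
    hdr += str(ns).ljust(4).encode()
    hdr += field(labels, 16)
    hdr += field([""] * ns, 80)          # transducer
    hdr += field(["mV"] * ns, 8)
    hdr += field([pmin] * ns, 8) + field([pmax] * ns, 8)
    hdr += field([dmin] * ns, 8) + field([dmax] * ns, 8)
    hdr += field([""] * ns, 80)          # prefiltering
    hdr += field([spr] * ns, 8)
    hdr += b" " * (32 * ns)
    scale = (pmax - pmin) / (dmax - dmin)
    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_rec):
            for ch in range(ns):
                seg = data_mv[ch, r * spr:(r + 1) * spr]
                dig = np.round((seg - pmin) / scale + dmin).astype("<i2")
                fh.write(dig.tobytes())
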