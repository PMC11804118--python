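"""Recording input, experiment metadata, and result persistence.

Recordings are continuous multi-channel voltage time series. Raw CSV/HDF5
values are assumed to be in recorder units and are divided by the
amplification gain at load time, so everything downstream works in mV.
Analysis results are written as self-describing JSON documents with two
top-level sections, ``experiment`` (the metadata that identifies the animal
and acquisition) and ``analysis`` (the parameters used and the outputs),
under a deterministic ``{analysis_type}_{animal_id}[_{channel}].{ext}``
naming scheme so repeated runs never collide across animals or channels.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "RecordingMetadata",
    "Recording",
    "read_recording",
    "result_path",
    "write_result",
    "read_result",
    "write_events_csv",
    "write_recording_csv",
]


class FormatError(ValueError):
    """File could not be parsed in the named format."""


class ShapeError(ValueError):
    """Channel/column count does not match the declared metadata."""


class DataError(ValueError):
    """Loaded samples contain non-finite values."""


@dataclass
class RecordingMetadata:
    """Experiment identification and acquisition parameters.

    Parameters
    ----------
    experiment_name, researcher, animal_id, group_id
        Free-text identifiers; ``animal_id`` and ``experiment_name`` drive
        output file naming and must be non-empty.
    n_channels
        Number of recorded channels (>= 1).
    fs
        Sampling frequency in Hz (> 0).
    gain
        Amplification gain of the acquisition chain (> 0); raw samples are
        divided by it to recover mV.
    filtered
        Whether the recording has already been band-pass filtered.
    """

    experiment_name: str
    researcher: str = ""
    animal_id: str = ""
    group_id: str = ""
    n_channels: int = 1
    fs: float = 1000.0
    gain: float = 1.0
    filtered: bool = False

    def __post_init__(self) -> None:
        if not self.experiment_name:
            raise ValueError("experiment_name must be non-empty")
        if not self.animal_id:
            raise ValueError("animal_id must be non-empty (it drives output naming)")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if not self.fs > 0:
            raise ValueError("fs must be > 0")
        if not self.gain > 0:
            raise ValueError("gain must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RecordingMetadata":
        return cls(**d)


@dataclass
class Recording:
    """A gain-corrected multi-channel LFP recording in mV.

    ``data`` is a ``(n_channels, n_samples)`` float array; time is seconds
    from recording start, samples are 0-based.
    """

    metadata: RecordingMetadata
    channel_labels: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if len(self.channel_labels) != self.metadata.n_channels:
            raise ShapeError(
                f"{len(self.channel_labels)} labels for "
                f"{self.metadata.n_channels} declared channels"
            )
        if self.data.shape[0] != self.metadata.n_channels:
            raise ShapeError(
                f"data has {self.data.shape[0]} channels, metadata declares "
                f"{self.metadata.n_channels}"
            )
        bad = ~np.isfinite(self.data)
        if bad.any():
            ch, idx = np.argwhere(bad)[0]
            raise DataError(
                f"non-finite sample in channel {self.channel_labels[ch]!r} "
                f"at index {idx}"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds (n_samples / fs)."""
        return self.n_samples / self.metadata.fs

    def channel(self, label: str) -> np.ndarray:
        """Return one channel's voltage series by label."""
        try:
            i = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(
                f"unknown channel {label!r}; have {self.channel_labels}"
            ) from None
        return self.data[i]


def _read_csv_matrix(path: Path) -> tuple[np.ndarray, Optional[list[str]]]:
    """Columns-per-channel CSV; a single non-numeric first row is a header
    whose names become the channel labels."""
    with open(path) as fh:
        first = fh.readline()
    tokens = [t.strip() for t in first.strip().split(",")]

    def _numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    header = 0 if tokens and not all(_numeric(t) for t in tokens) else None
    try:
        df = pd.read_csv(path, header=header)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"could not parse {path} as CSV: {exc}") from exc
    labels = [str(c) for c in df.columns] if header == 0 else None
    return df.to_numpy(dtype=float).T, labels  # -> channels x samples


def _read_hdf5_matrix(path: Path) -> tuple[np.ndarray, Optional[list[str]]]:
    """HDF5: either one 2-D channels-x-samples dataset or one dataset per channel."""
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise FormatError(f"could not open {path} as HDF5: {exc}") from exc
    with f:
        dsets = [k for k in f.keys() if isinstance(f[k], h5py.Dataset)]
        if not dsets:
            raise FormatError(f"{path} contains no HDF5 datasets")
        if len(dsets) == 1 and f[dsets[0]].ndim == 2:
            return np.asarray(f[dsets[0]], dtype=float), None
        arrs, labels = [], []
        for k in sorted(dsets):
            a = np.asarray(f[k], dtype=float)
            if a.ndim != 1:
                raise FormatError(
                    f"dataset {k!r} in {path} is {a.ndim}-D; expected one 1-D "
                    "dataset per channel or a single 2-D dataset"
                )
            arrs.append(a)
            labels.append(k)
        if len({a.shape[0] for a in arrs}) != 1:
            raise ShapeError(f"channel datasets in {path} have unequal lengths")
        return np.vstack(arrs), labels


def _read_edf(path: Path, metadata: RecordingMetadata):
    """EDF via mne; header fs and labels override the supplied metadata."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "EDF support requires the optional dependency 'mne' "
            "(pip install epilfp[edf])"
        ) from exc
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:
        raise FormatError(f"could not parse {path} as EDF: {exc}") from exc
    data = raw.get_data()  # volts for recognized channel units
    labels = list(raw.ch_names)
    fs = float(raw.info["sfreq"])
    if fs != metadata.fs:
        warnings.warn(
            f"EDF header fs={fs} Hz overrides metadata fs={metadata.fs} Hz",
            stacklevel=3,
        )
    if len(labels) != metadata.n_channels:
        warnings.warn(
            f"EDF header has {len(labels)} channels; metadata declared "
            f"{metadata.n_channels} — using the header",
            stacklevel=3,
        )
    return np.asarray(data, dtype=float) * 1e3, labels, fs  # V -> mV


def read_recording(
    path,
    format: str,
    metadata: RecordingMetadata,
    channel_labels: Optional[Sequence[str]] = None,
) -> Recording:
    """Load a recording and gain-correct it to mV.

    Parameters
    ----------
    path
        Input file.
    format
        One of ``"csv"``, ``"hdf5"``, ``"edf"``. CSV is one column per
        channel (optional header row); HDF5 is either a single 2-D
        channels-by-samples dataset or one 1-D dataset per channel. For
        CSV/HDF5, stored values are raw recorder units and are divided by
        ``metadata.gain``. For EDF the header is authoritative for sampling
        frequency and labels (a mismatch warns) and values are taken as
        already calibrated.
    metadata
        Acquisition metadata; ``n_channels`` must match the file for
        CSV/HDF5.
    channel_labels
        Optional labels; defaults to labels found in the file or
        ``ch0..chN-1``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format.lower()
    file_labels: Optional[list[str]] = None
    if fmt == "csv":
        data, file_labels = _read_csv_matrix(path)
        data = data / metadata.gain
    elif fmt in ("hdf5", "h5"):
        data, file_labels = _read_hdf5_matrix(path)
        data = data / metadata.gain
    elif fmt == "edf":
        data, file_labels, fs = _read_edf(path, metadata)
        metadata = RecordingMetadata(
            **{**metadata.to_dict(), "fs": fs, "n_channels": data.shape[0]}
        )
    else:
        raise ValueError(f"unknown format {format!r}; expected csv, hdf5 or edf")

    if data.shape[0] != metadata.n_channels:
        raise ShapeError(
            f"{path} has {data.shape[0]} channels but metadata declares "
            f"{metadata.n_channels}"
        )
    if channel_labels is not None:
        labels = list(channel_labels)
    elif file_labels is not None:
        labels = file_labels
    else:
        labels = [f"ch{i}" for i in range(metadata.n_channels)]
    return Recording(metadata=metadata, channel_labels=labels, data=data)


_SANITIZE_RE = re.compile(r"[^A-Za-z0-9._-]")


def _sanitize(text: str) -> str:
    return _SANITIZE_RE.sub("_", text)


def result_path(
    metadata: RecordingMetadata,
    analysis_type: str,
    channel: Optional[str] = None,
    ext: str = "json",
    outdir: Optional[Path] = None,
) -> Path:
    """Deterministic result file path: ``{analysis}_{animal}[_{channel}].{ext}``.

    The same inputs always produce the same path; the caller decides the
    overwrite policy. Characters illegal in file names are replaced by
    underscores.
    """
    if not analysis_type:
        raise ValueError("analysis_type must be non-empty")
    parts = [_sanitize(analysis_type), _sanitize(metadata.animal_id)]
    if channel is not None:
        parts.append(_sanitize(channel))
    name = "_".join(parts) + "." + ext.lstrip(".")
    return (Path(outdir) if outdir is not None else Path(".")) / name


def _jsonable(obj):
    """Recursively convert numpy containers and NaN to JSON-safe values."""
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (float, np.floating)):
        f = float(obj)
        return None if not np.isfinite(f) else f  # NaN flags -> null
    return obj


def write_result(result, path, metadata: RecordingMetadata) -> Path:
    """Serialize a result object to a two-section JSON document.

    The document has an ``experiment`` section (the metadata) and an
    ``analysis`` section (``type``, ``params``, ``results``); it round-trips
    losslessly through :func:`read_result`. Undefined statistics (NaN) are
    stored as JSON ``null``.
    """
    doc = {
        "experiment": metadata.to_dict(),
        "analysis": {
            "type": result.analysis_type,
            **_jsonable(result.to_dict()),
        },
    }
    path = Path(path)
    try:
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
    except OSError as exc:
        raise OSError(f"cannot write result to {path}: {exc}") from exc
    return path


def read_result(path):
    """Read a result document; returns ``(metadata, result_object)``.

    The concrete result type is dispatched on the ``analysis.type`` tag.
    """
    with open(path) as fh:
        doc = json.load(fh)
    metadata = RecordingMetadata.from_dict(doc["experiment"])
    analysis = dict(doc["analysis"])
    kind = analysis.pop("type")
    from .coincidence import CoincidenceResult
    from .correlation import CorrelationResult
    from .detection import DetectionResult
    from .morphology import MorphologyResult

    registry = {
        "detection": DetectionResult,
        "morphology": MorphologyResult,
        "coincidence": CoincidenceResult,
        "correlation": CorrelationResult,
    }
    try:
        cls = registry[kind]
    except KeyError:
        raise FormatError(f"unknown analysis type {kind!r} in {path}") from None
    return metadata, cls.from_dict(analysis)


def write_events_csv(events, path, channel: str = "") -> Path:
    """Write detected spike events as a CSV table.

    Columns: ``time_s``, ``amplitude_mV``, ``window_index``, ``channel``.
    """
    df = pd.DataFrame(
        {
            "time_s": [e.time for e in events],
            "amplitude_mV": [e.amplitude for e in events],
            "window_index": [e.window_index for e in events],
            "channel": channel,
        }
    )
    df.to_csv(path, index=False)
    return Path(path)


def write_recording_csv(recording: Recording, path) -> Path:
    """Write a recording as columns-per-channel CSV (mV, with header)."""
    df = pd.DataFrame(recording.data.T, columns=recording.channel_labels)
    df.to_csv(path, index=False)
    return Path(path)
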