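"""Shared data types and I/O for multichannel EEG recordings.

A :class:`Recording` is the pipeline's raw input: a channels × samples
matrix in microvolts, its sampling rate, 10/20 electrode labels, and a
list of trial events (target cue and movement onset, each tagged with a
reaching direction).  Recordings round-trip through a small versioned
HDF5 container; EDF/BDF files are read through :mod:`mne` when present.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd

DIRECTIONS = ("up", "down", "left", "right")
EVENT_KINDS = ("cue", "onset")

#: 64-channel extended 10/20 montage (BioSemi ActiveTwo layout).
BIOSEMI64 = (
    "Fp1", "AF7", "AF3", "F1", "F3", "F5", "F7", "FT7", "FC5", "FC3",
    "FC1", "C1", "C3", "C5", "T7", "TP7", "CP5", "CP3", "CP1", "P1",
    "P3", "P5", "P7", "P9", "PO7", "PO3", "O1", "Iz", "Oz", "POz",
    "Pz", "CPz", "Fpz", "Fp2", "AF8", "AF4", "AFz", "Fz", "F2", "F4",
    "F6", "F8", "FT8", "FC6", "FC4", "FC2", "FCz", "Cz", "C2", "C4",
    "C6", "T8", "TP8", "CP6", "CP4", "CP2", "P2", "P4", "P6", "P8",
    "P10", "PO8", "PO4", "O2",
)

#: Default 34-channel analysis subset: the extended 10/20 grid minus the
#: outer ring (temporal/occipital/frontopolar rows), i.e. the F/FC/C/CP/P
#: rows from the 5/6-position inward plus POz.  The study reports only the
#: count (34) and the intent (exclude peripheral and EOG-correlated
#: channels), so real-data users should override this list in config.
DEFAULT_CHANNEL_SUBSET = (
    "F3", "F1", "Fz", "F2", "F4",
    "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6",
    "P5", "P3", "P1", "Pz", "P2", "P4", "P6",
    "POz",
)

_CONTAINER_VERSION = 1


@dataclass(frozen=True)
class Event:
    """One protocol marker: a target cue or a movement onset."""

    kind: str
    sample: int
    trial_id: int
    direction: Optional[str] = None

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.direction is not None and self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass
class Recording:
    """Continuous multichannel EEG with trial events.

    Parameters
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    rate : float
        Sampling rate in Hz.
    channel_labels : sequence of str
        Unique 10/20 electrode names, one per signal row.
    events : list of Event
        Trial markers, kept sorted by sample index.
    """

    signal: np.ndarray
    rate: float
    channel_labels: list
    events: list = field(default_factory=list)

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels × samples)")
        self.channel_labels = list(self.channel_labels)
        if len(self.channel_labels) != self.signal.shape[0]:
            raise ValueError("n_channels != len(channel_labels)")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not self.rate > 0:
            raise ValueError("rate must be positive")
        n = self.signal.shape[1]
        for ev in self.events:
            if not 0 <= ev.sample < n:
                raise ValueError(f"event sample {ev.sample} outside [0, {n})")
        self.events = sorted(self.events, key=lambda e: (e.sample, e.kind))

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


@dataclass(frozen=True)
class BandSpec:
    """A frequency band and the feature representation extracted from it.

    Bands at or below the theta range carry direction information in their
    raw amplitude; higher bands are represented by their Hilbert envelope
    or instantaneous phase.  Mismatched combinations are allowed but warn.
    """

    name: str
    low: float
    high: float
    feature_mode: str = "amplitude"

    def __post_init__(self):
        if not 0 <= self.low < self.high:
            raise ValueError("band must satisfy 0 <= low < high")
        if self.feature_mode not in ("amplitude", "envelope", "phase"):
            raise ValueError(f"unknown feature mode {self.feature_mode!r}")
        if self.feature_mode == "amplitude" and self.low >= 7:
            warnings.warn(
                f"band {self.name!r}: amplitude features on a band starting at "
                f"{self.low} Hz; envelope/phase is the usual choice above 7 Hz",
                stacklevel=2,
            )
        if self.feature_mode in ("envelope", "phase") and self.low < 7:
            warnings.warn(
                f"band {self.name!r}: {self.feature_mode} features on a band "
                f"starting below 7 Hz; amplitude is the usual choice there",
                stacklevel=2,
            )


#: Default band set: slow cortical potentials plus the classical rhythms.
DEFAULT_BANDS = (
    BandSpec("scp", 0.1, 1.0, "amplitude"),
    BandSpec("delta", 1.0, 4.0, "amplitude"),
    BandSpec("theta", 4.0, 8.0, "amplitude"),
    BandSpec("alpha", 7.0, 13.0, "envelope"),
    BandSpec("beta", 13.0, 20.0, "envelope"),
    BandSpec("high_beta", 20.0, 30.0, "envelope"),
    BandSpec("low_gamma", 30.0, 45.0, "envelope"),
)

SCP_BAND = DEFAULT_BANDS[0]


@dataclass
class PipelineConfig:
    """Tunable parameters of the decoding pipeline (defaults follow the
    self-paced center-out protocol: 250 ms windows every 62.5 ms over
    [−2, 1] s around onset, 16 Hz feature rate, top-10 channels,
    chronological 5-fold CV, 10 permutation repetitions)."""

    channel_subset: tuple = DEFAULT_CHANNEL_SUBSET
    window_len: float = 0.25
    window_step: float = 0.0625
    analysis_span: tuple = (-2.0, 1.0)
    idle_span: tuple = (-1.0, 2.0)
    feature_rate: float = 16.0
    n_select_channels: int = 10
    n_folds: int = 5
    n_permutation_reps: int = 10
    alpha: float = 0.05
    consecutive_windows: int = 5
    shrinkage: float = 0.05
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("window_len", "window_step"):
            val = getattr(self, name)
            steps = val * self.feature_rate
            if abs(steps - round(steps)) > 1e-9:
                raise ValueError(f"{name}={val} not divisible by 1/feature_rate")
        if self.n_select_channels > len(self.channel_subset):
            raise ValueError("n_select_channels exceeds channel subset size")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def events_to_frame(events: Sequence[Event]) -> pd.DataFrame:
    """Tabulate events as (trial_id, kind, sample, direction)."""
    return pd.DataFrame(
        {
            "trial_id": [e.trial_id for e in events],
            "kind": [e.kind for e in events],
            "sample": [e.sample for e in events],
            "direction": [e.direction or "" for e in events],
        }
    )


def events_from_frame(frame: pd.DataFrame) -> list:
    out = []
    for row in frame.itertuples(index=False):
        direction = row.direction or None
        out.append(Event(kind=row.kind, sample=int(row.sample),
                         trial_id=int(row.trial_id), direction=direction))
    return out


def write_recording(rec: Recording, path) -> None:
    """Write a recording to the internal HDF5 container (layout v1).

    Layout: root attrs ``container_version``, ``rate``; datasets
    ``signal`` (float64, channels × samples), ``channel_labels`` (utf-8),
    and an ``events`` group of four parallel columns (trial_id, kind,
    sample, direction).  Object timestamps are disabled so a re-write of
    identical content is byte-stable.
    """
    path = Path(path)
    frame = events_to_frame(rec.events)
    with h5py.File(path, "w", track_order=True) as f:
        f.attrs["container_version"] = _CONTAINER_VERSION
        f.attrs["rate"] = float(rec.rate)
        f.create_dataset("signal", data=rec.signal, track_times=False)
        f.create_dataset(
            "channel_labels",
            data=np.array(rec.channel_labels, dtype=h5py.string_dtype()),
            track_times=False,
        )
        g = f.create_group("events", track_order=True)
        g.create_dataset("trial_id", data=frame["trial_id"].to_numpy(np.int64),
                         track_times=False)
        g.create_dataset("sample", data=frame["sample"].to_numpy(np.int64),
                         track_times=False)
        for col in ("kind", "direction"):
            g.create_dataset(
                col,
                data=np.array(frame[col], dtype=h5py.string_dtype()),
                track_times=False,
            )


def _read_internal(path) -> Recording:
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("container_version", -1))
        if version != _CONTAINER_VERSION:
            raise ValueError(f"unsupported container version {version}")
        signal = f["signal"][()]
        rate = float(f.attrs["rate"])
        labels = [s.decode() for s in f["channel_labels"][()]]
        g = f["events"]
        frame = pd.DataFrame(
            {
                "trial_id": g["trial_id"][()],
                "kind": [s.decode() for s in g["kind"][()]],
                "sample": g["sample"][()],
                "direction": [s.decode() for s in g["direction"][()]],
            }
        )
    return Recording(signal=signal, rate=rate, channel_labels=labels,
                     events=events_from_frame(frame))


def _read_mne(path, kind: str) -> Recording:
    # Lazy import: EDF/BDF support is optional and only needed for real data.
    import mne

    reader = mne.io.read_raw_bdf if kind == "bdf" else mne.io.read_raw_edf
    raw = reader(path, preload=True, verbose="error")
    signal = raw.get_data() * 1e6  # mne returns volts
    events = []
    trial_id = 0
    for onset_s, _dur, desc in zip(
        raw.annotations.onset, raw.annotations.duration,
        raw.annotations.description,
    ):
        parts = str(desc).split("/")
        if parts[0] not in EVENT_KINDS:
            continue
        direction = parts[1] if len(parts) > 1 and parts[1] in DIRECTIONS else None
        tid = int(parts[2]) if len(parts) > 2 else trial_id
        events.append(Event(kind=parts[0], sample=int(round(onset_s * raw.info["sfreq"])),
                            trial_id=tid, direction=direction))
        if parts[0] == "onset":
            trial_id += 1
    return Recording(signal=signal, rate=float(raw.info["sfreq"]),
                     channel_labels=list(raw.ch_names), events=events)


def read_recording(path, format: str = "internal") -> Recording:
    """Read a recording from ``internal`` (HDF5 container), ``edf`` or ``bdf``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "internal":
        return _read_internal(path)
    if format in ("edf", "bdf"):
        return _read_mne(path, format)
    raise ValueError(f"unknown format {format!r}")


def select_channels(rec: Recording, subset: Sequence[str]) -> Recording:
    """Restrict a recording to ``subset``, reordered to follow it."""
    missing = [name for name in subset if name not in rec.channel_labels]
    if missing:
        raise KeyError(f"channels not in recording: {missing}")
    idx = [rec.channel_labels.index(name) for name in subset]
    return replace(rec, signal=rec.signal[idx], channel_labels=list(subset),
                   events=list(rec.events))
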