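"""Epoching and sliding-window feature extraction.

Time conventions: trial-relative times are in seconds with the alignment
event at 0; sample indices are 0-based; every interval is half-open on
the left, (start, end], so a window's endpoint sample is included and
each window is labeled by its endpoint time.  An epoch over span
(t0, t1] at rate r holds round((t1−t0)·r) samples, sample k sitting at
t0 + (k+1)/r; the default intention epoch (−2, 1] s at 128 Hz is 384
samples ending exactly at +1 s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .preprocessing import BandSignal

logger = logging.getLogger(__name__)


@dataclass
class EpochSet:
    """Aligned per-trial segments with direction labels."""

    data: np.ndarray               # (n_trials, n_channels, n_samples)
    rate: float
    t0: float                      # span start (exclusive) relative to event
    alignment: str                 # "onset" | "cue"
    labels: np.ndarray             # direction per trial
    trial_ids: np.ndarray
    channel_labels: list
    representation: str = "amplitude"

    def __post_init__(self):
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials × channels × samples")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length != n_trials")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


@dataclass(frozen=True)
class WindowGrid:
    endpoints: Tuple[float, ...]   # s relative to alignment event
    window_len: float
    step: float

    def __post_init__(self):
        d = np.diff(self.endpoints)
        if len(self.endpoints) == 0:
            raise ValueError("empty grid")
        if len(d) and not np.allclose(d, self.step, atol=1e-9):
            raise ValueError("endpoints must be spaced by step")


@dataclass
class WindowFeatures:
    """Flattened per-trial features of one window (channel-major)."""

    window_endpoint: float
    matrix: np.ndarray                       # trials × (channels · points)
    provenance: List[Tuple[str, float]]      # (channel, time of sample) per column
    labels: np.ndarray


def epoch(band: BandSignal, events: Sequence, alignment: str,
          span: Tuple[float, float]) -> EpochSet:
    """Cut one trial per retained ``alignment`` event over ``span`` seconds.

    Trials whose span falls outside the recording are dropped with a log
    entry.  Event sample indices must already be expressed at the band
    signal's rate.
    """
    if alignment not in ("onset", "cue"):
        raise ValueError(f"unknown alignment {alignment!r}")
    rate = band.rate
    t0, t1 = span
    n_win = int(round((t1 - t0) * rate))
    trials, labels, ids = [], [], []
    n_total = band.signal.shape[-1]
    for ev in events:
        if ev.kind != alignment:
            continue
        start = ev.sample + int(round(t0 * rate)) + 1
        if start < 0 or start + n_win > n_total:
            logger.info("dropping trial %d: span outside recording", ev.trial_id)
            continue
        trials.append(band.signal[:, start : start + n_win])
        labels.append(ev.direction)
        ids.append(ev.trial_id)
    if not trials:
        raise ValueError("no trial fits the requested span")
    return EpochSet(
        data=np.stack(trials),
        rate=rate,
        t0=t0,
        alignment=alignment,
        labels=np.asarray(labels, dtype=object),
        trial_ids=np.asarray(ids, dtype=int),
        channel_labels=list(band.channel_labels or []),
        representation=band.representation,
    )


def make_grid(span: Tuple[float, float], window_len: float,
              step: float) -> WindowGrid:
    """Endpoints from span_start + window_len up to span_end, spaced by step."""
    t0, t1 = span
    if t1 - t0 < window_len - 1e-12:
        raise ValueError("span shorter than one window")
    n = int(np.floor((t1 - t0 - window_len) / step + 1e-9)) + 1
    endpoints = t0 + window_len + np.arange(n) * step
    if endpoints[-1] < t1 - 1e-9:
        logger.info("grid stops at %.4f s, short of span end %.4f s",
                    endpoints[-1], t1)
    return WindowGrid(endpoints=tuple(np.round(endpoints, 10)),
                      window_len=window_len, step=step)


def window_features(epochs: EpochSet, grid: WindowGrid, endpoint: float,
                    channels: Sequence[str], feature_rate: float,
                    phase_encoding: Optional[str] = None) -> WindowFeatures:
    """Flatten one window into trials × (channels · points) features.

    Decimation to ``feature_rate`` keeps every (rate/feature_rate)-th sample
    anchored at the window end, so the endpoint sample is always included.
    For phase epochs, ``phase_encoding="cos_sin"`` expands every column into
    a (cos φ, sin φ) pair; ``"raw_angle"`` (or None) keeps the angles.
    """
    if not np.any(np.isclose(grid.endpoints, endpoint, atol=1e-9)):
        raise ValueError(f"endpoint {endpoint} not in grid")
    rate = epochs.rate
    dec = rate / feature_rate
    if abs(dec - round(dec)) > 1e-9:
        raise ValueError("feature_rate must divide the epoch rate")
    dec = int(round(dec))
    ppw = int(round(grid.window_len * feature_rate))
    end_idx = int(round((endpoint - epochs.t0) * rate)) - 1
    first = end_idx - dec * (ppw - 1)
    if first < 0 or end_idx >= epochs.data.shape[-1]:
        raise ValueError(f"window ending at {endpoint} s exceeds the epoch span")
    sample_idx = end_idx - dec * np.arange(ppw)[::-1]
    times = epochs.t0 + (sample_idx + 1) / rate

    chan_idx = []
    for name in channels:
        try:
            chan_idx.append(epochs.channel_labels.index(name))
        except ValueError:
            raise KeyError(f"channel {name!r} not in epochs") from None

    block = epochs.data[:, chan_idx][:, :, sample_idx]   # trials × ch × ppw
    matrix = block.reshape(epochs.n_trials, -1)
    provenance = [(name, float(t)) for name in channels for t in times]

    if epochs.representation == "phase" and phase_encoding == "cos_sin":
        cols = [np.cos(matrix), np.sin(matrix)]
        matrix = np.empty((matrix.shape[0], matrix.shape[1] * 2))
        matrix[:, 0::2] = cols[0]
        matrix[:, 1::2] = cols[1]
        provenance = [p for pair in provenance for p in (pair, pair)]

    return WindowFeatures(window_endpoint=endpoint, matrix=matrix,
                          provenance=provenance, labels=epochs.labels.copy())


def features_to_frame(wf: WindowFeatures) -> pd.DataFrame:
    """Export a window's feature matrix with provenance column headers."""
    cols = [f"{name}@{t:+.4f}s" for name, t in wf.provenance]
    frame = pd.DataFrame(wf.matrix, columns=_dedupe(cols))
    frame.insert(0, "direction", wf.labels)
    return frame


def _dedupe(names: List[str]) -> List[str]:
    seen: dict = {}
    out = []
    for name in names:
        k = seen.get(name, 0)
        out.append(name if k == 0 else f"{name}#{k}")
        seen[name] = k + 1
    return out
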