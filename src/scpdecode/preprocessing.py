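"""Signal chain: common average reference, zero-phase filtering,
decimation, and per-band feature signals (amplitude / Hilbert envelope /
instantaneous phase).

All filters are Butterworth designs applied forward–backward through
second-order sections, so the effective magnitude response is the
squared single-pass response and the net group delay is zero.  Filter
orders: 4 for the wide 120 Hz low-pass, 2 for the narrow analysis bands
(a second-order band-pass at 0.1–1 Hz on 128 Hz data has a normalized
low edge of ~0.0016, where higher orders are numerically fragile).
Hilbert transforms run on the continuous recording, before epoching, so
epoch edges carry no analytic-signal edge distortion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .data_model import BandSpec

ANALYSIS_RATE = 128.0  # Hz; rate of all windowed analyses

LOWPASS_CUTOFF = 120.0  # Hz, wide anti-noise low-pass before decimation
LOWPASS_ORDER = 4
BAND_ORDER = 2


@dataclass(frozen=True)
class FilterSpec:
    kind: str                      # "lowpass" | "bandpass"
    cutoffs: Tuple[float, ...]     # Hz; one value for lowpass, two for bandpass
    order: int = 2
    zero_phase: bool = True

    def __post_init__(self):
        if self.kind not in ("lowpass", "bandpass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        n = 1 if self.kind == "lowpass" else 2
        if len(self.cutoffs) != n:
            raise ValueError(f"{self.kind} needs {n} cutoff(s)")


@dataclass
class BandSignal:
    """A band-limited feature signal (channels × samples)."""

    band: BandSpec
    signal: np.ndarray
    rate: float
    representation: str            # "amplitude" | "envelope" | "phase"
    channel_labels: Optional[list] = None


def apply_car(signal: np.ndarray) -> np.ndarray:
    """Common average reference: subtract the instantaneous cross-channel mean."""
    signal = np.asarray(signal, dtype=np.float64)
    if signal.ndim != 2 or signal.shape[0] < 2:
        raise ValueError("CAR needs at least 2 channels")
    return signal - signal.mean(axis=0, keepdims=True)


def _design(spec: FilterSpec, rate: float) -> np.ndarray:
    nyq = rate / 2.0
    if any(c >= nyq for c in spec.cutoffs):
        raise ValueError(f"cutoffs {spec.cutoffs} not below Nyquist {nyq} Hz")
    wn = spec.cutoffs[0] if spec.kind == "lowpass" else list(spec.cutoffs)
    sos = sps.butter(spec.order, wn, btype=spec.kind, fs=rate, output="sos")
    if not np.all(np.isfinite(sos)):
        raise ValueError(f"unstable filter design for {spec}")
    return sos


def zero_phase_filter(signal: np.ndarray, spec: FilterSpec,
                      rate: float) -> np.ndarray:
    """Forward–backward Butterworth filtering with generous reflect padding.

    Pad length is 3 × max(2 × order, one second of samples), capped at the
    signal length minus one; slow-band edge transients are long, hence the
    one-second floor.
    """
    signal = np.asarray(signal, dtype=np.float64)
    sos = _design(spec, rate)
    n = signal.shape[-1]
    if n <= 3 * spec.order:
        raise ValueError("signal too short for the requested filter order")
    padlen = min(n - 1, 3 * max(2 * spec.order, int(round(rate))))
    if not spec.zero_phase:
        return sps.sosfilt(sos, signal, axis=-1)
    return sps.sosfiltfilt(sos, signal, axis=-1, padlen=padlen)


def resample(signal: np.ndarray, rate_in: float, rate_out: float,
             anti_alias: bool = True) -> np.ndarray:
    """Decimate by an integer factor; output length floor(n·rate_out/rate_in).

    ``anti_alias=False`` skips the pre-decimation low-pass, for chains where
    an earlier wide low-pass already bounds the spectrum.
    """
    signal = np.asarray(signal, dtype=np.float64)
    factor = rate_in / rate_out
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(f"non-integer decimation factor {factor}")
    factor = int(round(factor))
    if factor == 1:
        return signal.copy()
    if anti_alias:
        spec = FilterSpec("lowpass", (0.45 * rate_out,), order=8)
        signal = zero_phase_filter(signal, spec, rate_in)
    n_out = signal.shape[-1] // factor
    return signal[..., : n_out * factor : factor].copy()


def band_features(signal: np.ndarray, band: BandSpec, rate: float,
                  channel_labels: Optional[Sequence[str]] = None,
                  envelope_mode: str = "modulus") -> BandSignal:
    """Band-pass then extract the band's feature representation.

    amplitude → the band-passed signal itself; envelope → modulus of the
    analytic signal (``envelope_mode="literal_rectified"`` instead takes the
    absolute value of the band-passed signal, i.e. full-wave rectification);
    phase → the analytic signal's instantaneous phase in (−π, π].
    """
    spec = FilterSpec("bandpass", (band.low, band.high), order=BAND_ORDER)
    filtered = zero_phase_filter(signal, spec, rate)
    if band.feature_mode == "amplitude":
        out = filtered
    elif band.feature_mode == "envelope":
        if envelope_mode == "modulus":
            out = np.abs(sps.hilbert(filtered, axis=-1))
        elif envelope_mode == "literal_rectified":
            out = np.abs(filtered)
        else:
            raise ValueError(f"unknown envelope mode {envelope_mode!r}")
    else:  # phase
        out = np.angle(sps.hilbert(filtered, axis=-1))
    labels = list(channel_labels) if channel_labels is not None else None
    return BandSignal(band=band, signal=out, rate=rate,
                      representation=band.feature_mode, channel_labels=labels)
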