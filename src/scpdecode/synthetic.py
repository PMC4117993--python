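"""Synthetic self-paced center-out pseudo-EEG.

Emulates the recording protocol the decoder assumes: 64-channel extended
10/20 EEG at 256 Hz, three runs of 80 trials (240 total) with balanced
up/down/left/right targets, a visual cue followed by a self-paced
movement onset at least 2 s later, and a direction-specific slow (<1 Hz)
potential building up over fronto-central/centro-parietal channels from
half a second before onset.  Background activity is 1/f-shaped noise
plus a small white component, per channel.  Trials are laid out on one
continuous timeline (jittered inter-trial gaps) so epoching code is
exercised realistically.

The planted component is a half-cosine ramp from zero to its peak over
[onset + effect_onset, onset], a plateau while the movement lasts, and a
half-cosine release; the waveform is band-limited to ``effect_band``
before injection.  Each direction multiplies the waveform by its own
zero-sum spatial gain pattern (an anterior–posterior gradient for
up/down, a left–right gradient for left/right), which makes the four
classes linearly separable at high SNR and survives common average
referencing.  ``snr`` scales the planted RMS (on a unit-gain channel)
relative to the background RMS inside the effect band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import signal as sps

from .data_model import BIOSEMI64, DIRECTIONS, Event, Recording

logger = logging.getLogger(__name__)

_EFFECT_ROW_FC = ("FC3", "FC1", "FCz", "FC2", "FC4")
_EFFECT_ROW_CP = ("CP3", "CP1", "CPz", "CP2", "CP4")


def default_effect_channels() -> Dict[str, List[Tuple[str, float]]]:
    """Direction → (channel, gain) map over a fronto-parietal 10-channel set.

    up/down use an anterior–posterior gradient, left/right a left–right
    gradient; every pattern sums to zero and has max |gain| = 1.
    """
    chans = _EFFECT_ROW_FC + _EFFECT_ROW_CP
    ap = [1.0] * 5 + [-1.0] * 5
    lr = [-1.0, -0.5, 0.0, 0.5, 1.0] * 2
    return {
        "up": list(zip(chans, ap)),
        "down": list(zip(chans, [-g for g in ap])),
        "left": list(zip(chans, lr)),
        "right": list(zip(chans, [-g for g in lr])),
    }


@dataclass
class SynthConfig:
    """Generator settings; defaults reproduce the study protocol scale."""

    n_trials: int = 240
    n_channels: int = 64
    rate: float = 256.0
    cue_to_onset_shape: float = 4.0      # gamma shape; mean = 2 + shape*scale
    cue_to_onset_scale: float = 0.25     # → mean latency ≈ 3.0 s, min 2.0 s
    effect_channels: Optional[Dict[str, List[Tuple[str, float]]]] = None
    effect_onset: float = -0.5           # s before movement onset
    effect_band: Tuple[float, float] = (0.1, 1.0)
    snr: float = 1.0
    one_over_f_exponent: float = 1.0
    pink_sigma: float = 10.0             # µV RMS of the 1/f component
    white_sigma: float = 0.5             # µV RMS of the white component
    early_start_fraction: float = 0.04
    move_duration: float = 1.0           # s of sustained plateau after onset
    pre_cue_gap: Tuple[float, float] = (2.0, 4.0)   # jittered inter-trial gap
    post_trial_pad: float = 2.0          # s after onset before next gap
    rng_seed: int = 0

    def __post_init__(self):
        if self.effect_channels is None:
            self.effect_channels = default_effect_channels()
        if self.effect_onset >= 0:
            raise ValueError("effect_onset must be negative (pre-onset)")
        if self.snr < 0:
            raise ValueError("snr must be nonnegative")
        if not 0 <= self.early_start_fraction < 1:
            raise ValueError("early_start_fraction must be in [0, 1)")


@dataclass
class GroundTruth:
    """Per-trial truth for parameter-recovery tests."""

    directions: List[str]
    cue_samples: np.ndarray
    onset_samples: np.ndarray
    early_start: np.ndarray            # bool per trial
    effect_channels: Dict[str, List[Tuple[str, float]]]
    effect_onset: float
    effect_amplitude: float            # µV scale applied to unit-gain channels

    @property
    def n_retained(self) -> int:
        return int((~self.early_start).sum())

    @property
    def planted_channel_names(self) -> List[str]:
        names: List[str] = []
        for pairs in self.effect_channels.values():
            for name, gain in pairs:
                if gain != 0 and name not in names:
                    names.append(name)
        return names


def _one_over_f_noise(rng: np.random.Generator, n_channels: int, n: int,
                      exponent: float, sigma: float) -> np.ndarray:
    """Gaussian noise with power spectral density ∝ f^-exponent, RMS=sigma."""
    freqs = np.fft.rfftfreq(n, d=1.0)          # relative frequencies
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    out = np.empty((n_channels, n))
    for c in range(n_channels):
        spec = (rng.standard_normal(len(freqs))
                + 1j * rng.standard_normal(len(freqs))) * shape
        x = np.fft.irfft(spec, n=n)
        rms = np.sqrt(np.mean(x**2))
        out[c] = x * (sigma / rms)
    return out


def _balanced_directions(rng: np.random.Generator, n_trials: int) -> List[str]:
    reps = -(-n_trials // len(DIRECTIONS))
    labels = np.tile(np.array(DIRECTIONS, dtype=object), reps)[:n_trials]
    return list(rng.permutation(labels))


def _effect_waveform(t_rel: np.ndarray, effect_onset: float,
                     move_duration: float, release: float = 0.5) -> np.ndarray:
    """Ramp–plateau–release profile as a function of time relative to onset."""
    w = np.zeros_like(t_rel)
    ramp = (t_rel >= effect_onset) & (t_rel < 0)
    w[ramp] = 0.5 * (1 - np.cos(np.pi * (t_rel[ramp] - effect_onset) / -effect_onset))
    plateau = (t_rel >= 0) & (t_rel < move_duration)
    w[plateau] = 1.0
    down = (t_rel >= move_duration) & (t_rel < move_duration + release)
    w[down] = 0.5 * (1 + np.cos(np.pi * (t_rel[down] - move_duration) / release))
    return w


def generate_recording(cfg: SynthConfig) -> Tuple[Recording, GroundTruth]:
    """Generate one continuous recording plus its ground truth.

    Deterministic given ``cfg.rng_seed``.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    rate = cfg.rate
    labels = list(BIOSEMI64[: cfg.n_channels])
    label_index = {name: i for i, name in enumerate(labels)}
    for pairs in cfg.effect_channels.values():
        for name, _gain in pairs:
            if name not in label_index:
                raise KeyError(f"effect channel {name!r} not in montage")

    directions = _balanced_directions(rng, cfg.n_trials)
    early = rng.random(cfg.n_trials) < cfg.early_start_fraction
    latency = 2.0 + rng.gamma(cfg.cue_to_onset_shape, cfg.cue_to_onset_scale,
                              size=cfg.n_trials)
    latency[early] = rng.uniform(1.0, 2.0, size=int(early.sum()))

    # Timeline: gap → cue → (latency) → onset → movement + pad → next gap.
    cue_times = np.empty(cfg.n_trials)
    onset_times = np.empty(cfg.n_trials)
    cursor = 2.0  # lead-in so the first idle epoch fits
    gaps = rng.uniform(*cfg.pre_cue_gap, size=cfg.n_trials)
    for i in range(cfg.n_trials):
        cue_times[i] = cursor + gaps[i]
        onset_times[i] = cue_times[i] + latency[i]
        cursor = onset_times[i] + cfg.post_trial_pad
    n_samples = int(np.ceil((cursor + 2.0) * rate))

    signal = _one_over_f_noise(rng, cfg.n_channels, n_samples,
                               cfg.one_over_f_exponent, cfg.pink_sigma)
    if cfg.white_sigma > 0:
        signal += cfg.white_sigma * rng.standard_normal(signal.shape)

    # Per-direction drivers: sum of trial waveforms, then band-limited once.
    amp = 0.0
    if cfg.snr > 0:
        t = np.arange(n_samples) / rate
        drivers = {d: np.zeros(n_samples) for d in DIRECTIONS}
        active = np.zeros(n_samples, dtype=bool)
        for i in range(cfg.n_trials):
            lo = int((onset_times[i] + cfg.effect_onset - 0.5) * rate)
            hi = int((onset_times[i] + cfg.move_duration + 1.0) * rate)
            seg = slice(max(lo, 0), min(hi, n_samples))
            w = _effect_waveform(t[seg] - onset_times[i], cfg.effect_onset,
                                 cfg.move_duration)
            drivers[directions[i]][seg] += w
            active[seg] |= w > 0
        # Causal band-limiting: the planted potential must not precede the
        # neural event it models, so no zero-phase (backward) filtering here.
        sos = sps.butter(2, cfg.effect_band, btype="bandpass", fs=rate,
                         output="sos")
        for d in DIRECTIONS:
            drivers[d] = sps.sosfilt(sos, drivers[d])
        # Scale: unit-gain planted RMS over active support = snr × background
        # RMS in the effect band (averaged over the planted channels).
        planted_idx = sorted({label_index[nm]
                              for pairs in cfg.effect_channels.values()
                              for nm, g in pairs if g != 0})
        bg = sps.sosfiltfilt(sos, signal[planted_idx], axis=-1)
        bg_rms = float(np.sqrt(np.mean(bg**2)))
        total = sum(drivers.values())
        drv_rms = float(np.sqrt(np.mean(total[active] ** 2)))
        amp = cfg.snr * bg_rms / max(drv_rms, 1e-30)
        for d in DIRECTIONS:
            for name, gain in cfg.effect_channels[d]:
                signal[label_index[name]] += amp * gain * drivers[d]

    events = []
    for i in range(cfg.n_trials):
        events.append(Event("cue", int(round(cue_times[i] * rate)), i,
                            directions[i]))
        events.append(Event("onset", int(round(onset_times[i] * rate)), i,
                            directions[i]))
    rec = Recording(signal=signal, rate=rate, channel_labels=labels,
                    events=events)
    truth = GroundTruth(
        directions=directions,
        cue_samples=np.array([round(c * rate) for c in cue_times], dtype=int),
        onset_samples=np.array([round(o * rate) for o in onset_times], dtype=int),
        early_start=early,
        effect_channels=cfg.effect_channels,
        effect_onset=cfg.effect_onset,
        effect_amplitude=amp,
    )
    return rec, truth


def discard_early_starts(rec: Recording, min_latency: float = 2.0) -> Recording:
    """Drop trials whose cue-to-onset latency is below ``min_latency`` seconds.

    Only the events list changes; the signal is untouched.
    """
    cues = {e.trial_id: e for e in rec.events if e.kind == "cue"}
    onsets = {e.trial_id: e for e in rec.events if e.kind == "onset"}
    orphans = set(onsets) - set(cues)
    if orphans:
        raise ValueError(f"onset events without cue for trials {sorted(orphans)}")
    bad = {
        tid for tid, on in onsets.items()
        if on.sample - cues[tid].sample < min_latency * rec.rate
    }
    if bad:
        logger.info("discarding %d early-start trial(s): %s", len(bad), sorted(bad))
    kept = [e for e in rec.events if e.trial_id not in bad]
    return replace(rec, events=kept)
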