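"""End-to-end orchestration of the decoding chain.

``preprocess_recording`` runs: early-start discard → channel subset →
common average reference → 120 Hz zero-phase low-pass → decimation to
128 Hz → band filter and feature extraction (amplitude/envelope/phase).
Event sample indices are rescaled to the analysis rate.

``decode_directions`` adds the full quantitative surface: time-specific
decoding curve over the intention period, permutation chance level and
early-detection time, best pre-onset window selection, and the frozen
selected classifier's sensitivity (intention) and specificity (idle)
curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .data_model import BandSpec, Event, PipelineConfig, Recording, SCP_BAND, \
    select_channels
from .preprocessing import (ANALYSIS_RATE, BandSignal, FilterSpec,
                            LOWPASS_CUTOFF, LOWPASS_ORDER, apply_car,
                            band_features, resample, zero_phase_filter)
from .synthetic import discard_early_starts
from .evaluation import (ChanceLevel, DecodingCurve, SelectedClassifier,
                         chance_level, early_detection, run_selected,
                         run_time_specific, select_best_window)
from .windows import epoch, make_grid


def _rescale_events(events, rate_in: float, rate_out: float):
    if rate_in == rate_out:
        return list(events)
    return [
        Event(e.kind, int(round(e.sample * rate_out / rate_in)), e.trial_id,
              e.direction)
        for e in events
    ]


def preprocess_recording(rec: Recording, cfg: PipelineConfig,
                         band: BandSpec = SCP_BAND,
                         drop_early: bool = True,
                         envelope_mode: str = "modulus"):
    """Run the signal chain; returns (BandSignal at 128 Hz, rescaled events).

    The wide low-pass doubles as the anti-alias filter for the final
    decimation (all analysis bands sit well below the decimated Nyquist),
    so ``resample`` is called without an extra pre-filter.  Recordings
    above 256 Hz are first brought down to 256 Hz with proper anti-alias
    filtering.
    """
    if drop_early:
        rec = discard_early_starts(rec)
    rec = select_channels(rec, cfg.channel_subset)
    x, rate = rec.signal, rec.rate
    if rate > 256:
        x = resample(x, rate, 256.0, anti_alias=True)
        rate = 256.0
    x = apply_car(x)
    if rate > ANALYSIS_RATE:
        if rate / 2 > LOWPASS_CUTOFF:
            x = zero_phase_filter(
                x, FilterSpec("lowpass", (LOWPASS_CUTOFF,), LOWPASS_ORDER),
                rate)
        x = resample(x, rate, ANALYSIS_RATE, anti_alias=False)
    band_sig = band_features(x, band, ANALYSIS_RATE,
                             channel_labels=rec.channel_labels,
                             envelope_mode=envelope_mode)
    events = _rescale_events(rec.events, rec.rate, ANALYSIS_RATE)
    return band_sig, events


@dataclass
class DecodingResult:
    """Bundle of everything one band's decoding run produces."""

    band: BandSpec
    intention: DecodingCurve             # time-specific, onset-aligned
    chance: ChanceLevel
    detection_time: Optional[float]
    selected: SelectedClassifier
    sensitivity: DecodingCurve           # frozen model, intention period
    specificity: DecodingCurve           # frozen model, idle period


def decode_directions(rec: Recording, cfg: PipelineConfig,
                      band: BandSpec = SCP_BAND,
                      phase_encoding: Optional[str] = None,
                      chance_mode: str = "reselect") -> DecodingResult:
    """Full single-band analysis: curves, chance, detection, selected model."""
    if band.feature_mode == "phase" and phase_encoding is None:
        phase_encoding = "cos_sin"
    band_sig, events = preprocess_recording(rec, cfg, band)
    grid = make_grid(cfg.analysis_span, cfg.window_len, cfg.window_step)
    intention_epochs = epoch(band_sig, events, "onset", cfg.analysis_span)
    curve = run_time_specific(intention_epochs, grid, cfg,
                              phase_encoding=phase_encoding)
    chance = chance_level(intention_epochs, grid, cfg, seed=cfg.rng_seed,
                          mode=chance_mode, phase_encoding=phase_encoding)
    if len(grid.endpoints) >= cfg.consecutive_windows:
        detection = early_detection(curve, chance, alpha=cfg.alpha,
                                    k_consecutive=cfg.consecutive_windows)
    else:
        detection = None
        curve.chance_mean = chance.mean
        curve.chance_distribution = chance.per_window
    selected = select_best_window(curve)
    sensitivity = run_selected(selected, intention_epochs, grid, cfg)

    idle_grid = make_grid(cfg.idle_span, cfg.window_len, cfg.window_step)
    idle_epochs = epoch(band_sig, events, "cue", cfg.idle_span)
    specificity = run_selected(selected, idle_epochs, idle_grid, cfg)
    return DecodingResult(band=band, intention=curve, chance=chance,
                          detection_time=detection, selected=selected,
                          sensitivity=sensitivity, specificity=specificity)
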