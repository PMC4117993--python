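"""Phase-feature decoding: instantaneous phase through the identical
selection/classification/evaluation chain.

Circular phase angles do not feed well into a linear classifier across
the ±π wrap, so the default encoding expands every phase sample into a
(cos φ, sin φ) pair (doubling the column count); ``raw_angle`` keeps the
angles for literal replication.  Phase is extracted from the continuous
band-passed signal before epoching and is invariant to any global
amplitude scaling of the recording.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence

from .data_model import BandSpec, PipelineConfig, Recording
from .evaluation import DecodingCurve, run_time_specific
from .pipeline import preprocess_recording
from .windows import epoch, make_grid

PHASE_ENCODINGS = ("cos_sin", "raw_angle")


@dataclass(frozen=True)
class PhaseEncoding:
    mode: str = "cos_sin"

    def __post_init__(self):
        if self.mode not in PHASE_ENCODINGS:
            raise ValueError(f"unknown phase encoding {self.mode!r}")


def as_phase_band(band: BandSpec) -> BandSpec:
    """The same frequency range with phase extraction."""
    if band.feature_mode == "phase":
        return band
    return BandSpec(f"{band.name}_phase", band.low, band.high, "phase")


def phase_pipeline(rec: Recording, bands: Sequence[BandSpec],
                   encoding: PhaseEncoding, cfg: PipelineConfig
                   ) -> Dict[str, DecodingCurve]:
    """Time-specific decoding curves from instantaneous-phase features."""
    enc = encoding.mode if encoding.mode == "cos_sin" else None
    grid = make_grid(cfg.analysis_span, cfg.window_len, cfg.window_step)
    out: Dict[str, DecodingCurve] = {}
    for band in bands:
        pband = as_phase_band(band)
        band_sig, events = preprocess_recording(rec, cfg, pband)
        epochs = epoch(band_sig, events, "onset", cfg.analysis_span)
        out[pband.name] = run_time_specific(epochs, grid, cfg,
                                            phase_encoding=enc)
    return out
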