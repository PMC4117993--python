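import numpy as np
import pytest

from scpdecode import (PipelineConfig, SynthConfig, epoch, generate_recording,
                       make_grid, preprocess_recording)


@pytest.fixture(scope="session")
def small_run():
    """One small high-SNR synthetic recording, preprocessed to SCP epochs.

    40 trials keep the session fast while leaving ~9 trials per class.
    """
    cfg = SynthConfig(n_trials=40, snr=3.0, rng_seed=3)
    rec, truth = generate_recording(cfg)
    pcfg = PipelineConfig(rng_seed=3, n_permutation_reps=3)
    band_sig, events = preprocess_recording(rec, pcfg)
    epochs = epoch(band_sig, events, "onset", pcfg.analysis_span)
    return {
        "cfg": cfg,
        "rec": rec,
        "truth": truth,
        "pcfg": pcfg,
        "band_sig": band_sig,
        "events": events,
        "epochs": epochs,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_epochs(n_trials=40, n_channels=6, n_samples=64, rate=128.0,
                t0=-0.5, seed=0, labels=None, data=None):
    """Small synthetic EpochSet straight from arrays (no signal chain)."""
    from scpdecode import EpochSet

    rng = np.random.default_rng(seed)
    if data is None:
        data = rng.standard_normal((n_trials, n_channels, n_samples))
    if labels is None:
        labels = np.array(["up", "down", "left", "right"] * (n_trials // 4 + 1),
                          dtype=object)[:n_trials]
    return EpochSet(
        data=data,
        rate=rate,
        t0=t0,
        alignment="onset",
        labels=np.asarray(labels, dtype=object),
        trial_ids=np.arange(n_trials),
        channel_labels=[f"C{i}" for i in range(n_channels)],
    )
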