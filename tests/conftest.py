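"""Shared fixtures: small seeded signals, trials and datasets."""

import numpy as np
import pytest

from tsann import EEGTrial, SynthConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trial(rows, fs=128.0, label="l1", trial_id="t0"):
    rows = np.asarray(rows, dtype=float)
    return EEGTrial(
        data=rows,
        fs=fs,
        channels=[f"ch{i}" for i in range(rows.shape[0])],
        label=label,
        trial_id=trial_id,
    )


def sine_trial(freqs_phases, fs=128.0, duration=10.0, label="l1", trial_id="t0"):
    """One trial whose channels are unit sinusoids (freq, phase) pairs."""
    t = np.arange(int(round(duration * fs))) / fs
    rows = [np.sin(2 * np.pi * f * t + p) for f, p in freqs_phases]
    return make_trial(rows, fs=fs, label=label, trial_id=trial_id)


@pytest.fixture
def small_synth_trials():
    """Tiny strongly-coupled dataset: 6 channels, 12 trials/class, 6 s @ 64 Hz."""
    cfg = SynthConfig(
        n_channels=6, fs=64.0, duration_s=6.0, trials_per_class=12,
        coupled_l1=(0, 1, 2), coupled_l2=(3, 4, 5), seed=7,
    )
    return cfg, generate_dataset(cfg)
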