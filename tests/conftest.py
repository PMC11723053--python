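"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from mieog.data_model import ChannelMeta, EpochedDataset, Modality
from mieog.synthetic_data import SimulationConfig, generate


def recovery_config(seed: int, **overrides) -> SimulationConfig:
    """Planted-recovery study conditions: a scaled-down pooled-subject
    recording (12 channels, 4 classes, 480 trials of 1 s at 128 Hz) with a
    strong planted band-power effect on three EEG channels."""
    base = dict(
        n_eeg=9, n_eog=3, n_classes=4, n_trials=480, n_samples=128,
        sampling_rate=128.0, informative_channels=[2, 4, 6],
        modulation_depth=0.8, oscillation_amplitude=0.8, eog_leakage=0.0,
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig.preset("custom", **base)


@pytest.fixture(scope="session")
def small_sim():
    """Small informative dataset with EOG leakage: 8 channels, 40 trials."""
    config = SimulationConfig.preset(
        "custom", n_eeg=5, n_eog=3, n_classes=4, n_trials=40, n_samples=128,
        sampling_rate=128.0, informative_channels=[1, 3], modulation_depth=0.8,
        oscillation_amplitude=0.8, eog_leakage=0.5, seed=7,
    )
    return generate(config)


@pytest.fixture()
def small_dataset(small_sim):
    dataset, _ = small_sim
    return dataset


def make_dataset(data: np.ndarray, labels, fs: float = 100.0,
                 eog_names: tuple[str, ...] = ()) -> EpochedDataset:
    """Wrap a raw array in an EpochedDataset with simple channel metadata."""
    n_channels = data.shape[1]
    channels = []
    n_eeg = n_channels - len(eog_names)
    for i in range(n_channels):
        if i < n_eeg:
            channels.append(ChannelMeta(f"EEG{i}", Modality.EEG, i))
        else:
            channels.append(ChannelMeta(eog_names[i - n_eeg], Modality.EOG, i))
    labels = np.asarray(labels)
    n_classes = int(labels.max()) + 1
    return EpochedDataset(
        data=data, labels=labels,
        class_names=[f"class{i}" for i in range(n_classes)],
        channels=channels, sampling_rate=fs,
    )
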