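"""Spectral estimation and filtering primitives.

Multitaper PSD estimation (the estimator behind the per-class spectral
overviews), a zero-phase FIR band-pass used ahead of spatial filtering, and
train-statistics z-scoring for model input.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from mne.time_frequency import psd_array_multitaper
from scipy.signal import filtfilt, firwin

from .data_model import EpochedDataset

__all__ = ["SpectralEstimate", "multitaper_psd", "bandpass_filter", "zscore_normalize"]


@dataclass
class SpectralEstimate:
    """Multitaper PSD: ``power[channel, freq]`` in µV²/Hz (linear or dB)."""

    frequencies: np.ndarray
    power: np.ndarray  # (n_channels, n_freqs)
    in_decibels: bool = False

    def to_db(self) -> "SpectralEstimate":
        """10·log10 conversion; zero power maps to -inf."""
        if self.in_decibels:
            return self
        with np.errstate(divide="ignore"):
            db = 10.0 * np.log10(self.power)
        return SpectralEstimate(self.frequencies, db, in_decibels=True)

    def to_frame(self, channel_names: list[str] | None = None) -> pd.DataFrame:
        names = channel_names or [f"ch{i}" for i in range(self.power.shape[0])]
        records = [
            {"frequency_hz": f, "channel": names[c], "power": self.power[c, i]}
            for c in range(self.power.shape[0])
            for i, f in enumerate(self.frequencies)
        ]
        return pd.DataFrame.from_records(records)


def multitaper_psd(
    dataset: EpochedDataset,
    fmin: float = 0.1,
    fmax: float = 40.0,
    per_class: bool = False,
    bandwidth: float | None = None,
) -> SpectralEstimate | dict[int, SpectralEstimate]:
    """Trial-averaged multitaper PSD per channel over [fmin, fmax].

    The taper count follows from the normalized half-bandwidth (default 4,
    i.e. ``bandwidth = 8 * fs / n_samples`` Hz); with ``per_class=True`` one
    estimate is returned per class label.
    """
    fs = dataset.sampling_rate
    if not fmin < fmax:
        raise ValueError("fmin must be < fmax")
    if fmax >= fs / 2:
        raise ValueError(f"fmax ({fmax} Hz) must be below Nyquist ({fs / 2} Hz)")
    if bandwidth is None:
        bandwidth = 8.0 * fs / dataset.n_samples  # half-bandwidth NW = 4

    def _estimate(data: np.ndarray) -> SpectralEstimate:
        psd, freqs = psd_array_multitaper(
            data, fs, fmin=fmin, fmax=fmax, bandwidth=bandwidth,
            adaptive=False, normalization="full", verbose=False,
        )
        return SpectralEstimate(frequencies=freqs, power=psd.mean(axis=0))

    if not per_class:
        return _estimate(dataset.data)
    return {
        int(cls): _estimate(dataset.data[dataset.labels == cls])
        for cls in np.unique(dataset.labels)
    }


def _fir_bandpass(low: float, high: float, fs: float) -> np.ndarray:
    """Linear-phase FIR band-pass; order ~ 3.3·fs/low, forced odd."""
    numtaps = int(np.ceil(3.3 * fs / low)) | 1
    return firwin(numtaps, [low, high], pass_zero=False, fs=fs)


def bandpass_filter(dataset: EpochedDataset, low: float = 7.0, high: float = 35.0) -> EpochedDataset:
    """Zero-phase FIR band-pass (forward-backward) applied per trial/channel.

    Defaults to 7–35 Hz, the band where motor-imagery activation lives.
    """
    fs = dataset.sampling_rate
    if not 0 < low < high < fs / 2:
        raise ValueError(
            f"band ({low}, {high}) Hz invalid for sampling rate {fs} Hz (Nyquist {fs / 2})"
        )
    taps = _fir_bandpass(low, high, fs)
    padlen = min(3 * len(taps), dataset.n_samples - 1)
    filtered = filtfilt(taps, [1.0], dataset.data, axis=-1, padlen=padlen)
    return replace(dataset, data=filtered)


def zscore_normalize(
    train: EpochedDataset, test: EpochedDataset
) -> tuple[EpochedDataset, EpochedDataset]:
    """Standardize both sets with per-channel mean/SD computed on train only.

    Statistics pool all train trials and samples per channel.  A
    zero-variance channel is an error (named in the message).
    """
    mean = train.data.mean(axis=(0, 2), keepdims=True)
    sd = train.data.std(axis=(0, 2), keepdims=True)
    dead = np.flatnonzero(sd.ravel() == 0)
    if dead.size:
        names = [train.channels[i].name for i in dead]
        raise ValueError(f"zero-variance channel(s) in training data: {names}")
    return (
        replace(train, data=(train.data - mean) / sd),
        replace(test, data=(test.data - mean) / sd),
    )
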