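"""Lightweight band-power classifier used as a trainer/model handle.

Wrapper-style importance methods (permutation importance, random search)
only need *some* classifier whose accuracy reflects which channels carry
class information.  The band-power LDA here — log-variance of band-passed
trials per channel, fed to linear discriminant analysis — is the classic
fast baseline for oscillatory motor-imagery signals and keeps the wrapper
loops cheap; the deep model can be plugged into the same protocols.
"""

from __future__ import annotations

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .data_model import EpochedDataset, SplitSpec, split_trials
from .signal_processing import bandpass_filter

__all__ = ["BandPowerLDA", "accuracy_of", "band_power_trainer"]


class BandPowerLDA:
    """Log band-power features (default 7-35 Hz) + linear discriminant."""

    def __init__(self, band: tuple[float, float] = (7.0, 35.0)):
        self.band = band
        self._lda = LinearDiscriminantAnalysis()
        self._fs: float | None = None
        self.n_channels: int | None = None

    def _features(self, data: np.ndarray, fs: float) -> np.ndarray:
        from scipy.signal import filtfilt

        from .signal_processing import _fir_bandpass

        lo, hi = self.band
        if hi >= fs / 2:  # clamp for low sampling rates
            hi = 0.95 * fs / 2
        taps = _fir_bandpass(lo, hi, fs)
        padlen = min(3 * len(taps), data.shape[-1] - 1)
        filtered = filtfilt(taps, [1.0], data, axis=-1, padlen=padlen)
        return np.log(filtered.var(axis=-1) + 1e-12)

    def fit(self, train: EpochedDataset) -> "BandPowerLDA":
        self._fs = train.sampling_rate
        self.n_channels = train.n_channels
        self._lda.fit(self._features(train.data, self._fs), train.labels)
        return self

    def predict(self, data: np.ndarray) -> np.ndarray:
        if self._fs is None:
            raise RuntimeError("classifier not fitted")
        if data.shape[1] != self.n_channels:
            raise ValueError(
                f"model expects {self.n_channels} channels, got {data.shape[1]}"
            )
        return self._lda.predict(self._features(data, self._fs))


def accuracy_of(model, dataset: EpochedDataset) -> float:
    """Fraction of correctly predicted trials, in [0, 1]."""
    return float(np.mean(model.predict(dataset.data) == dataset.labels))


def band_power_trainer(dataset: EpochedDataset, seed: int = 0,
                       band: tuple[float, float] = (7.0, 35.0)) -> float:
    """Train/evaluate the band-power LDA on an internal 80/20 split.

    Usable directly as the ``trainer`` handle of random search.
    """
    train, test = split_trials(dataset, SplitSpec(seed=seed))
    model = BandPowerLDA(band=band).fit(train)
    return accuracy_of(model, test)
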