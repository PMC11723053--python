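"""Synthetic EEG/EOG generator with planted, recoverable structure.

Emulates the statistical features the importance analyses rely on:

* a 1/f^a Gaussian background per channel (frequency-domain amplitude
  shaping of white noise, so the target spectrum holds in expectation),
* class-dependent band-power modulation (an ERD/ERS analogue) on a set of
  *informative* channels — each class scales the variance of a band-limited
  oscillation rather than adding an evoked waveform,
* EOG channels built as leakage mixtures of the neural oscillation source
  plus ocular transients (smooth low-frequency Hann pulses) and their own
  background.

The planted effect matrix is returned as :class:`GroundTruth` so recovery
tests can check that importance methods find the planted channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import ChannelMeta, EpochedDataset, Modality
from .signal_processing import multitaper_psd

__all__ = ["SimulationConfig", "GroundTruth", "generate", "spectral_check"]

_D1_CLASSES = ["left_hand", "right_hand", "feet", "tongue"]
_D2_CLASSES = [
    "left_hand", "right_hand", "feet", "hands", "rest",
    "left_hand_right_foot", "right_hand_left_foot",
]

#: Band assignments cycled over classes: (low Hz, high Hz, modulation sign).
#: Mu (8-12 Hz) and beta (12-30 Hz) with power increase (+1) or decrease
#: (-1, the ERD analogue) give mutually distinguishable class signatures.
_DEFAULT_BAND_CYCLE = [(8.0, 12.0, +1), (12.0, 30.0, +1), (8.0, 12.0, -1), (12.0, 30.0, -1)]


@dataclass
class SimulationConfig:
    """Layout, spectral and effect parameters of a simulated recording.

    The two presets reproduce the public benchmark layouts exactly:
    ``dataset1_like`` is 22 EEG + 3 EOG at 250 Hz, 4 balanced classes x 144
    trials (576 total) of 1000 samples; ``dataset2_like`` is 60 EEG + 2 EOG
    at 200 Hz, 7 classes x 80 trials (560 total) of 800 samples.
    """

    layout: str = "dataset1_like"
    n_eeg: int = 22
    n_eog: int = 3
    n_classes: int = 4
    n_trials: int = 576
    n_samples: int = 1000
    sampling_rate: float = 250.0
    spectral_exponent: float = 1.0
    informative_channels: list[int] = field(default_factory=list)
    modulation_depth: float = 0.5
    bands: dict[int, tuple[float, float, int]] = field(default_factory=dict)
    eog_leakage: float = 0.5
    artifact_rate: float = 0.2       # ocular transients per second
    artifact_amplitude: float = 5.0  # x noise_sd
    oscillation_amplitude: float = 0.5  # x noise_sd, baseline band SD
    balanced_pairs: bool = True      # ERS on one pair channel, ERD on the other
    noise_sd: float = 10.0           # microvolts
    seed: int = 0

    @classmethod
    def preset(cls, layout: str, **overrides) -> "SimulationConfig":
        if layout == "dataset1_like":
            base = dict(layout=layout, n_eeg=22, n_eog=3, n_classes=4, n_trials=576,
                        n_samples=1000, sampling_rate=250.0,
                        informative_channels=[7, 9, 11])
        elif layout == "dataset2_like":
            base = dict(layout=layout, n_eeg=60, n_eog=2, n_classes=7, n_trials=560,
                        n_samples=800, sampling_rate=200.0,
                        informative_channels=[26, 28, 30])
        elif layout == "custom":
            base = dict(layout=layout)
        else:
            raise ValueError(f"unknown layout {layout!r}")
        base.update(overrides)
        return cls(**base)

    def __post_init__(self) -> None:
        if self.n_trials % self.n_classes != 0:
            raise ValueError("n_trials must be a multiple of n_classes (balanced design)")
        if not 0.0 <= self.modulation_depth <= 1.0:
            raise ValueError("modulation_depth must be in [0, 1]")
        if self.artifact_rate < 0:
            raise ValueError("artifact_rate must be >= 0")
        if not 0.0 <= self.eog_leakage <= 1.0:
            raise ValueError("eog_leakage must be in [0, 1]")
        if not self.bands:
            self.bands = {
                k: _DEFAULT_BAND_CYCLE[k % len(_DEFAULT_BAND_CYCLE)]
                for k in range(self.n_classes)
            }
        nyq = self.sampling_rate / 2
        for k, (lo, hi, sign) in self.bands.items():
            if not 0 < lo < hi < nyq:
                raise ValueError(
                    f"band for class {k} = ({lo}, {hi}) Hz outside (0, {nyq}) Hz"
                )
            if sign not in (-1, +1):
                raise ValueError("modulation sign must be -1 or +1")
        bad = [c for c in self.informative_channels if not 0 <= c < self.n_eeg + self.n_eog]
        if bad:
            raise ValueError(f"informative channel indices out of range: {bad}")
        if self.informative_channels and self.n_classes - 1 < len(self.informative_channels):
            raise ValueError(
                "need n_classes - 1 >= n_informative so every planted channel "
                "is modulated by at least one class"
            )

    @property
    def n_channels(self) -> int:
        return self.n_eeg + self.n_eog


@dataclass
class GroundTruth:
    """Planted effects: which channels are informative and how much.

    ``effect_matrix[k, c]`` is the variance scaling applied to channel c's
    band oscillation under class k; informative channels are exactly those
    with a non-unit entry somewhere.
    """

    informative_channels: list[int]
    effect_matrix: np.ndarray  # (n_classes, n_channels)


def _shaped_noise(rng: np.random.Generator, shape: tuple[int, ...], n_samples: int,
                  amp_profile: np.ndarray, target_sd: float) -> np.ndarray:
    """Gaussian noise with rFFT amplitude profile ``amp_profile``, SD ``target_sd``.

    The profile is scaled analytically so the time-domain variance equals
    ``target_sd**2`` in expectation (spectrum exact in expectation, not per
    realization).
    """
    n_freq = n_samples // 2 + 1
    prof = np.asarray(amp_profile, dtype=float)
    # expected time-domain variance of irfft of hermitian spectrum with
    # independent CN(0, 2 prof^2) interior bins
    interior = prof[1:-1] if n_samples % 2 == 0 else prof[1:]
    edge = prof[-1] ** 2 if n_samples % 2 == 0 else 0.0
    exp_var = (4.0 * np.sum(interior ** 2) + prof[0] ** 2 + edge) / n_samples ** 2
    if exp_var == 0:
        return np.zeros(shape + (n_samples,))
    scale = target_sd / np.sqrt(exp_var)
    spec = (rng.standard_normal(shape + (n_freq,)) +
            1j * rng.standard_normal(shape + (n_freq,))) * (prof * scale)
    return np.fft.irfft(spec, n=n_samples, axis=-1)


def _one_over_f_profile(n_samples: int, fs: float, exponent: float) -> np.ndarray:
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    prof = np.zeros_like(freqs)
    prof[1:] = freqs[1:] ** (-exponent / 2.0)
    return prof


def _band_profile(n_samples: int, fs: float, lo: float, hi: float) -> np.ndarray:
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    return ((freqs >= lo) & (freqs <= hi)).astype(float)


def _ocular_transients(rng: np.random.Generator, n_trials: int, n_samples: int,
                       fs: float, rate: float, amplitude: float) -> np.ndarray:
    """Randomly timed smooth Hann deflections, 0.5-2 s long."""
    out = np.zeros((n_trials, n_samples))
    if rate == 0:
        return out
    duration_s = n_samples / fs
    n_events = rng.poisson(rate * duration_s, size=n_trials)
    for t in range(n_trials):
        for _ in range(n_events[t]):
            width = int(rng.uniform(0.5, 2.0) * fs)
            start = int(rng.uniform(-0.5 * width, n_samples - 0.5 * width))
            pulse = amplitude * rng.choice([-1.0, 1.0]) * np.hanning(width)
            a, b = max(start, 0), min(start + width, n_samples)
            out[t, a:b] += pulse[a - start:b - start]
    return out


def generate(config: SimulationConfig) -> tuple[EpochedDataset, GroundTruth]:
    """Simulate an epoched dataset; fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    C, L, fs = config.n_channels, config.n_samples, config.sampling_rate
    n = config.n_trials
    per_class = n // config.n_classes
    labels = np.repeat(np.arange(config.n_classes), per_class)
    labels = rng.permutation(labels)

    bg_prof = _one_over_f_profile(L, fs, config.spectral_exponent)
    data = _shaped_noise(rng, (n, C), L, bg_prof, config.noise_sd)

    # class-dependent band oscillations on informative channels (an ERD/ERS
    # analogue).  Every informative channel carries baseline oscillations in
    # each band used by any class; class 0 is the unmodulated baseline and
    # class k >= 1 applies an opposite-sign modulation to a contiguous pair
    # of planted channels starting at (k-1) mod n_informative (power up on
    # one, down on the other) — mimicking the lateralized ERD/ERS pattern
    # of motor imagery where task-specific sensorimotor regions overlap
    # between tasks.  The balanced pair keeps total power nearly
    # class-independent while every planted channel contributes to the
    # margin of some class pair (classes sharing a channel differ in band
    # or modulation direction).
    effect = np.ones((config.n_classes, C))
    osc_sd = config.oscillation_amplitude * config.noise_sd
    info = list(config.informative_channels)
    # per-planted-channel oscillation sources that can leak into EOG
    sources = np.zeros((n, max(len(info), 1), L))
    if info:
        distinct_bands = sorted({(lo, hi) for lo, hi, _ in config.bands.values()})
        for k, (lo, hi, sign) in config.bands.items():
            idx = np.flatnonzero(labels == k)
            if idx.size == 0:
                continue
            mult = np.ones(len(info))
            if k >= 1:
                mult[(k - 1) % len(info)] = 1.0 + sign * config.modulation_depth
                if len(info) > 1:
                    pair_sign = -sign if config.balanced_pairs else sign
                    mult[k % len(info)] = 1.0 + pair_sign * config.modulation_depth
            effect[k, info] = mult
            total = np.zeros((idx.size, len(info), L))
            for blo, bhi in distinct_bands:
                prof = _band_profile(L, fs, blo, bhi)
                osc = _shaped_noise(rng, (idx.size, len(info)), L, prof, osc_sd)
                if (blo, bhi) == (lo, hi):
                    osc *= np.sqrt(mult)[None, :, None]
                total += osc
            data[np.ix_(idx, info)] += total
            sources[idx] = total

    # EOG channels: independent background already present; add leakage +
    # ocular transients.  Each EOG electrode leaks a steeply
    # distance-attenuated mixture of the planted sources with its own
    # dominant source (periocular electrodes sit at different positions),
    # so the EOG array collectively reflects the class-dependent band
    # power whenever leakage is non-zero.
    eog_idx = list(range(config.n_eeg, C))
    n_src = sources.shape[1]
    for pos, j in enumerate(eog_idx):
        if info:
            w = 4.0 ** -((np.arange(n_src) - pos) % n_src).astype(float)
            w = w / np.sqrt((w ** 2).sum())
            data[:, j, :] += config.eog_leakage * np.einsum(
                "nil,i->nl", sources, w)
        data[:, j, :] += _ocular_transients(
            rng, n, L, fs, config.artifact_rate,
            config.artifact_amplitude * config.noise_sd,
        )

    if config.layout == "dataset1_like":
        class_names = _D1_CLASSES
        eog_names = [f"EOG{i}" for i in range(config.n_eog)]
    elif config.layout == "dataset2_like":
        class_names = _D2_CLASSES
        eog_names = ["VEOG", "HEOG"][: config.n_eog]
    else:
        class_names = [f"class{i}" for i in range(config.n_classes)]
        eog_names = [f"EOG{i}" for i in range(config.n_eog)]
    channels = [ChannelMeta(f"EEG{i}", Modality.EEG, i) for i in range(config.n_eeg)]
    channels += [
        ChannelMeta(eog_names[i], Modality.EOG, config.n_eeg + i)
        for i in range(config.n_eog)
    ]

    dataset = EpochedDataset(
        data=data, labels=labels, class_names=class_names, channels=channels,
        sampling_rate=fs, subject_id=f"sim-{config.layout}-{config.seed}",
    )
    return dataset, GroundTruth(informative_channels=info, effect_matrix=effect)


def spectral_check(dataset: EpochedDataset, fit_range: tuple[float, float] = (2.0, 40.0)) -> np.ndarray:
    """Per-channel log-log slope of the multitaper PSD over ``fit_range``.

    A background with power ∝ 1/f^a yields a slope of about -a.
    """
    lo, hi = fit_range
    nyq = dataset.sampling_rate / 2
    if not 0 < lo < hi < nyq:
        raise ValueError(f"fit range ({lo}, {hi}) must lie inside (0, {nyq}) Hz")
    est = multitaper_psd(dataset, fmin=lo, fmax=hi)
    if est.frequencies.size < 5:
        raise ValueError(
            f"only {est.frequencies.size} PSD bins in fit range; need >= 5"
        )
    logf = np.log10(est.frequencies)
    slopes = np.array([
        np.polyfit(logf, np.log10(est.power[c]), 1)[0]
        for c in range(dataset.n_channels)
    ])
    return slopes
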