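"""Core domain types for epoched EEG/EOG trial data.

The universal currency of the package is :class:`EpochedDataset`: a
``trials x channels x samples`` array of microvolt amplitudes together with
integer class labels and per-channel metadata.  Channel metadata carries a
modality tag (EEG vs EOG) which drives the EOG-aware selection and reporting
done elsewhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Modality",
    "ChannelMeta",
    "EpochedDataset",
    "SplitSpec",
    "AccuracyTable",
    "select_channels",
    "split_trials",
    "summarize_table",
    "DATASET1_ALIASES",
]


class Modality(str, Enum):
    EEG = "EEG"
    EOG = "EOG"


#: Alias map from the index-style names used for the 25-channel 4-class
#: recording (22 EEG + 3 EOG) to standard 10-20 montage names.  The three
#: motor-cortex electrodes sit at fixed positions of that montage.
#: Overridable wherever names are resolved.
DATASET1_ALIASES: dict[str, str] = {"C3": "EEG7", "Cz": "EEG9", "C4": "EEG11"}


@dataclass(frozen=True)
class ChannelMeta:
    """One recording channel: name, modality tag and array position."""

    name: str
    modality: Modality
    index: int

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError(f"channel index must be >= 0, got {self.index}")


@dataclass
class EpochedDataset:
    """Epoched multi-channel trials with class labels.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Signal amplitudes in microvolts.
    labels : ndarray of int, shape (n_trials,)
        Class labels in ``0 .. n_classes-1``; every class must occur.
    class_names : list of str
        Human-readable class names, one per class.
    channels : list of ChannelMeta
        Per-channel metadata; indices must be ``0 .. n_channels-1``.
    sampling_rate : float
        Sampling frequency in Hz, strictly positive.
    subject_id : str, optional
    """

    data: np.ndarray
    labels: np.ndarray
    class_names: list[str]
    channels: list[ChannelMeta]
    sampling_rate: float
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3-D (trials, channels, samples), got shape {self.data.shape}")
        n_trials, n_channels, n_samples = self.data.shape
        if n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if self.labels.shape != (n_trials,):
            raise ValueError(
                f"labels length {self.labels.shape} inconsistent with {n_trials} trials"
            )
        if len(self.channels) != n_channels:
            raise ValueError(
                f"{len(self.channels)} channel descriptors for {n_channels} data channels"
            )
        if [c.index for c in self.channels] != list(range(n_channels)):
            raise ValueError("channel indices must be 0..C-1 in order, no gaps")
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        n_classes = len(self.class_names)
        present = np.unique(self.labels)
        if n_classes == 0 or not np.array_equal(present, np.arange(n_classes)):
            raise ValueError(
                f"every class 0..{n_classes - 1} must occur at least once; saw {present.tolist()}"
            )

    # -- convenience -------------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    def eog_indices(self) -> list[int]:
        return [c.index for c in self.channels if c.modality is Modality.EOG]

    def eeg_indices(self) -> list[int]:
        return [c.index for c in self.channels if c.modality is Modality.EEG]

    def subset_trials(self, idx: np.ndarray) -> "EpochedDataset":
        """Dataset restricted to the given trial indices (order kept)."""
        return replace(self, data=self.data[idx], labels=self.labels[idx])


@dataclass(frozen=True)
class SplitSpec:
    """Train/test partition specification.

    ``train_fraction`` defaults to 0.8 (the 80/20 protocol); stratified
    splitting preserves class balance and is the default.
    """

    train_fraction: float = 0.8
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


def select_channels(dataset: EpochedDataset, names: Sequence[str],
                    aliases: Mapping[str, str] | None = None) -> EpochedDataset:
    """Restrict a dataset to the named channels, in the given order.

    ``aliases`` maps alternative names (e.g. 10-20 labels like ``"C3"``) to
    the dataset's native channel names; :data:`DATASET1_ALIASES` is applied
    by default when the native name is absent.

    Raises
    ------
    KeyError
        If a name (after alias resolution) is not a channel of the dataset,
        listing the available names.
    """
    alias_map = DATASET1_ALIASES if aliases is None else dict(aliases)
    by_name = {c.name: c for c in dataset.channels}
    picked: list[ChannelMeta] = []
    for raw in names:
        name = raw if raw in by_name else alias_map.get(raw, raw)
        if name not in by_name:
            raise KeyError(
                f"unknown channel {raw!r}; available: {sorted(by_name)}"
            )
        picked.append(by_name[name])
    idx = [c.index for c in picked]
    new_channels = [
        ChannelMeta(name=c.name, modality=c.modality, index=i)
        for i, c in enumerate(picked)
    ]
    return replace(dataset, data=dataset.data[:, idx, :], channels=new_channels)


def _apportion(counts: np.ndarray, fraction: float) -> np.ndarray:
    """Per-class train counts via largest-remainder apportionment.

    The total equals ``round(fraction * n_trials)`` (banker's rounding) while
    each class receives either floor or ceil of its exact share, so class
    proportions are preserved within rounding.
    """
    exact = counts * fraction
    base = np.floor(exact).astype(int)
    total = int(np.round(float(counts.sum() * fraction)))
    short = total - int(base.sum())
    if short > 0:
        order = np.argsort(-(exact - base), kind="stable")  # ties -> lowest class
        base[order[:short]] += 1
    elif short < 0:
        order = np.argsort(exact - base, kind="stable")
        base[order[:-short]] -= 1
    return base


def split_trials(dataset: EpochedDataset, spec: SplitSpec) -> tuple[EpochedDataset, EpochedDataset]:
    """Random train/test partition of trials, deterministic given the seed.

    With ``stratified=True`` (default) the split is drawn per class and
    per-class train counts are apportioned so that the overall train size is
    ``round(train_fraction * n_trials)``.  Index sets are disjoint and
    exhaustive.
    """
    rng = np.random.default_rng(spec.seed)
    n = dataset.n_trials
    if spec.stratified:
        classes, counts = np.unique(dataset.labels, return_counts=True)
        if counts.min() < 2:
            bad = classes[counts < 2].tolist()
            raise ValueError(
                f"stratified split needs >= 2 trials per class; classes {bad} have fewer"
            )
        n_train_per_class = _apportion(counts, spec.train_fraction)
        train_idx: list[np.ndarray] = []
        test_idx: list[np.ndarray] = []
        for cls, k in zip(classes, n_train_per_class):
            members = np.flatnonzero(dataset.labels == cls)
            perm = rng.permutation(members)
            train_idx.append(perm[:k])
            test_idx.append(perm[k:])
        tr = np.sort(np.concatenate(train_idx))
        te = np.sort(np.concatenate(test_idx))
    else:
        k = int(np.round(n * spec.train_fraction))
        perm = rng.permutation(n)
        tr = np.sort(perm[:k])
        te = np.sort(perm[k:])
    return dataset.subset_trials(tr), dataset.subset_trials(te)


def summarize_table(rows: Sequence[float]) -> tuple[float, float, float]:
    """Mean, median and population standard deviation of per-subject accuracies.

    The median of an even count is the midpoint of the two central values and
    the standard deviation divides by N (population form) — the conventions
    under which published per-subject accuracy tables reproduce their printed
    summary rows.
    """
    values = np.asarray(list(rows), dtype=float)
    if values.size == 0:
        raise ValueError("summarize_table needs at least one row")
    return float(values.mean()), float(np.median(values)), float(values.std(ddof=0))


@dataclass
class AccuracyTable:
    """Per-subject accuracies (%) per named configuration, with summary rows.

    ``rows`` maps ``(subject_id, configuration)`` to accuracy in [0, 100].
    Summaries (mean / median / population std per configuration) are always
    recomputed from the rows.
    """

    rows: dict[tuple[str, str], float] = field(default_factory=dict)

    def add(self, subject: str, configuration: str, accuracy: float) -> None:
        if not 0.0 <= accuracy <= 100.0:
            raise ValueError(f"accuracy {accuracy} outside [0, 100]")
        self.rows[(subject, configuration)] = float(accuracy)

    def configurations(self) -> list[str]:
        return sorted({cfg for _, cfg in self.rows})

    def column(self, configuration: str) -> dict[str, float]:
        return {s: a for (s, cfg), a in self.rows.items() if cfg == configuration}

    def summary(self) -> dict[str, dict[str, float]]:
        out: dict[str, dict[str, float]] = {}
        for cfg in self.configurations():
            mean, median, std = summarize_table(list(self.column(cfg).values()))
            out[cfg] = {"mean": mean, "median": median, "std": std}
        return out

    def to_frame(self) -> pd.DataFrame:
        subjects = sorted({s for s, _ in self.rows})
        frame = pd.DataFrame(
            {cfg: [self.rows.get((s, cfg), np.nan) for s in subjects]
             for cfg in self.configurations()},
            index=subjects,
        )
        frame.index.name = "subject"
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)
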