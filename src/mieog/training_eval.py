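"""Training protocol and the subject-wise evaluation grid.

One training run: stratified 80/20 split, per-channel z-scoring with train
statistics, Adam + cross-entropy for a fixed number of epochs, held-out
accuracy recorded after every epoch (thinnable via ``eval_every`` when
only the final skill matters).  The reported figure of merit is the
*peak* test accuracy over epochs — reproducing the published protocol,
which selects on the test trace and is therefore optimistic; an honest mode
peak-picks on a validation split carved out of the training data instead.

The evaluation grid runs named channel configurations (e.g. all-EEG,
EOG-only, reduced EEG + EOG) over several independent splits and averages
the peak accuracies into an :class:`~mieog.data_model.AccuracyTable` row.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .data_model import AccuracyTable, EpochedDataset, SplitSpec, select_channels, split_trials
from .neural_model import ModelConfig, MultiKernelCNN, build_model
from .nn import Adam, softmax_cross_entropy
from .signal_processing import zscore_normalize

__all__ = ["TrainConfig", "TrainResult", "train_once", "evaluate_configuration"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (Adam, cross-entropy)."""

    learning_rate: float = 1e-3
    epochs: int = 500
    batch_size: int = 64
    n_splits: int = 5
    seed: int = 0
    normalize: bool = True
    honest_validation: bool = False  # peak-pick on a validation split, not test
    eval_every: int = 1              # evaluate held-out accuracy every k epochs

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


@dataclass
class TrainResult:
    """Per-epoch held-out accuracy trace (%) with its peak.

    ``channel_mean``/``channel_sd`` hold the train-set normalization applied
    to the model's input (None when normalization was off); new data must be
    standardized with them before being fed to ``model``.
    """

    test_accuracy_per_epoch: np.ndarray
    peak_test_accuracy: float
    model: MultiKernelCNN
    split_seed: int
    channel_mean: np.ndarray | None = None
    channel_sd: np.ndarray | None = None

    def normalize(self, data: np.ndarray) -> np.ndarray:
        if self.channel_mean is None:
            return data
        return (data - self.channel_mean) / self.channel_sd

    def __post_init__(self) -> None:
        assert np.isclose(self.peak_test_accuracy, self.test_accuracy_per_epoch.max())


def _accuracy(model: MultiKernelCNN, data: np.ndarray, labels: np.ndarray) -> float:
    return 100.0 * float(np.mean(model.predict(data) == labels))


def train_once(
    dataset: EpochedDataset,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig = TrainConfig(),
    split: SplitSpec | None = None,
) -> TrainResult:
    """Train the model on one random split; deterministic given the seeds."""
    split = split or SplitSpec(seed=train_config.seed)
    train, test = split_trials(dataset, split)
    if train_config.honest_validation:
        train, val = split_trials(train, SplitSpec(seed=split.seed + 7919))
    else:
        val = test
    channel_mean = channel_sd = None
    if train_config.normalize:
        channel_mean = train.data.mean(axis=(0, 2), keepdims=True)
        channel_sd = train.data.std(axis=(0, 2), keepdims=True)
        train, val = zscore_normalize(train, val)
        if not train_config.honest_validation:
            test = val
    if model_config is None:
        model_config = ModelConfig(
            n_channels=dataset.n_channels,
            n_samples=dataset.n_samples,
            n_classes=dataset.n_classes,
        )
    else:
        model_config = replace(
            model_config,
            n_channels=dataset.n_channels,
            n_samples=dataset.n_samples,
            n_classes=dataset.n_classes,
        )
    model = build_model(model_config, seed=train_config.seed)
    optimizer = Adam(model.params(), learning_rate=train_config.learning_rate)
    rng = np.random.default_rng(train_config.seed + 2)

    eval_epochs = [e for e in range(train_config.epochs)
                   if (e + 1) % train_config.eval_every == 0
                   or e == train_config.epochs - 1]
    trace = np.zeros(len(eval_epochs))
    n = train.n_trials
    for epoch in range(train_config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, train_config.batch_size):
            idx = order[start:start + train_config.batch_size]
            logits = model.forward(train.data[idx], training=True)
            loss, grad = softmax_cross_entropy(logits, train.labels[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged (loss={loss}) at epoch {epoch}; "
                    "reduce the learning rate or normalize the input"
                )
            optimizer.zero_grad()
            model.backward(grad)
            optimizer.step()
        if epoch in eval_epochs:
            trace[eval_epochs.index(epoch)] = _accuracy(model, val.data, val.labels)
    return TrainResult(
        test_accuracy_per_epoch=trace,
        peak_test_accuracy=float(trace.max()),
        model=model,
        split_seed=split.seed,
        channel_mean=channel_mean,
        channel_sd=channel_sd,
    )


def evaluate_configuration(
    dataset: EpochedDataset,
    channel_sets: Mapping[str, Sequence[str]],
    train_config: TrainConfig = TrainConfig(),
    model_config: ModelConfig | None = None,
) -> AccuracyTable:
    """Run each named channel configuration over ``n_splits`` random splits.

    The mean of the per-split peak test accuracies becomes the row of the
    accuracy table for this dataset's subject.  The five split seeds derive
    deterministically from the master seed (``seed + split index``).
    """
    table = AccuracyTable()
    subject = dataset.subject_id or "S1"
    for name, channels in channel_sets.items():
        sub = select_channels(dataset, list(channels))
        peaks = []
        for i in range(train_config.n_splits):
            result = train_once(
                sub, model_config=model_config, train_config=train_config,
                split=SplitSpec(seed=train_config.seed + i),
            )
            peaks.append(result.peak_test_accuracy)
        table.add(subject, name, float(np.mean(peaks)))
    return table
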