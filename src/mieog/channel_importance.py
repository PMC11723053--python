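"""Five channel-importance/selection methods for epoched EEG/EOG data.

Filter-based: pairwise mutual information between EOG and EEG channels, and
common-spatial-pattern (CSP) activations.  Wrapper-based: permutation
importance and random channel-subset search.  Embedded: the learned channel
attention gates of the deep model.  All methods emit an
:class:`ImportanceResult` with a per-channel score vector and a
deterministic ranking (descending score, ties broken by ascending channel
index).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .data_model import EpochedDataset
from .signal_processing import bandpass_filter

__all__ = [
    "MutualInformationResult",
    "CSPResult",
    "ImportanceResult",
    "entropy",
    "mutual_information",
    "mi_matrix",
    "csp_fit",
    "csp_from_covariances",
    "csp_pattern_activation",
    "csp_importance",
    "permutation_importance",
    "random_search",
    "attention_importance",
    "attention_experiment",
]


# ---------------------------------------------------------------------------
# shared result containers
# ---------------------------------------------------------------------------

def _ranking(scores: np.ndarray) -> np.ndarray:
    """Indices by descending score; ties by ascending index; NaN last."""
    keys = np.where(np.isnan(scores), -np.inf, scores)
    return np.lexsort((np.arange(len(scores)), -keys))


@dataclass
class ImportanceResult:
    """Per-channel importance scores of one method."""

    method: str
    scores: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def ranking(self) -> np.ndarray:
        return _ranking(np.asarray(self.scores, dtype=float))

    def top(self, k: int) -> list[int]:
        return self.ranking[:k].tolist()

    def to_frame(self, dataset: EpochedDataset | None = None) -> pd.DataFrame:
        scores = np.asarray(self.scores, dtype=float)
        rank_of = np.empty(len(scores), dtype=int)
        rank_of[self.ranking] = np.arange(len(scores))
        frame = pd.DataFrame({
            "channel": (dataset.channel_names if dataset is not None
                        else list(range(len(scores)))),
            "modality": ([c.modality.value for c in dataset.channels]
                         if dataset is not None else ""),
            "score": scores,
            "rank": rank_of,
        })
        return frame.sort_values("rank").reset_index(drop=True)


# ---------------------------------------------------------------------------
# mutual information
# ---------------------------------------------------------------------------

def entropy(p: Sequence[float]) -> float:
    """Shannon entropy −Σ p·log2 p in bits, with 0·log 0 = 0."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities must sum to 1, got {p.sum()}")
    nz = p[p > 0]
    return float(-np.sum(nz * np.log2(nz)))


def _joint_histogram(x: np.ndarray, y: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width joint histogram over each variable's own range."""
    joint, _, _ = np.histogram2d(x, y, bins=n_bins)
    return joint / joint.sum()


def mutual_information(x: Sequence[float], y: Sequence[float], n_bins: int = 64) -> float:
    """Plug-in histogram estimate of I(X;Y) = H(X) + H(Y) − H(X,Y), in bits.

    Marginals are the row/column sums of the joint histogram, so symmetry
    and the bound I ≤ min(H(X), H(Y)) hold exactly.  A constant input
    occupies a single bin and yields I = 0 with a warning.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} samples, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input occupies a single bin; MI = 0", stacklevel=2)
        return 0.0
    pxy = _joint_histogram(x, y, n_bins)
    hx = entropy(pxy.sum(axis=1))
    hy = entropy(pxy.sum(axis=0))
    hxy = entropy(pxy.ravel())
    return hx + hy - hxy


@dataclass
class MutualInformationResult:
    """Pairwise EOG-EEG mutual information in bits."""

    matrix: np.ndarray              # (n_eog, n_eeg)
    eog_names: list[str]
    eeg_names: list[str]
    marginal_entropies: dict[str, float]
    n_bins: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.eog_names, columns=self.eeg_names)


def mi_matrix(dataset: EpochedDataset, n_bins: int = 64) -> MutualInformationResult:
    """Mutual information between every EOG and every EEG channel.

    Each channel's samples are the concatenation of all its trials' time
    series.  Entries are non-negative and bounded by the smaller marginal
    entropy.
    """
    eog = dataset.eog_indices()
    eeg = dataset.eeg_indices()
    if not eog:
        raise ValueError("dataset has no EOG channels")
    if not eeg:
        raise ValueError("dataset has no EEG channels")
    flat = dataset.data.transpose(1, 0, 2).reshape(dataset.n_channels, -1)
    matrix = np.zeros((len(eog), len(eeg)))
    for i, ei in enumerate(eog):
        for j, ej in enumerate(eeg):
            matrix[i, j] = mutual_information(flat[ei], flat[ej], n_bins=n_bins)
    marginals = {}
    for c in range(dataset.n_channels):
        hist, _ = np.histogram(flat[c], bins=n_bins)
        marginals[dataset.channels[c].name] = entropy(hist / hist.sum())
    return MutualInformationResult(
        matrix=matrix,
        eog_names=[dataset.channels[i].name for i in eog],
        eeg_names=[dataset.channels[j].name for j in eeg],
        marginal_entropies=marginals,
        n_bins=n_bins,
    )


# ---------------------------------------------------------------------------
# common spatial patterns
# ---------------------------------------------------------------------------

@dataclass
class CSPResult:
    """Spatial filters/patterns of one two-class (or one-vs-rest) contrast.

    Columns of ``filters_w`` solve the generalized eigenproblem
    ``S w = λ R w`` with ``eigenvalues_lambda`` descending; ``patterns`` is
    the inverse-transpose of the filter matrix, describing source-to-sensor
    mixing.
    """

    filters_w: np.ndarray           # (C, C), columns = filters
    eigenvalues_lambda: np.ndarray  # (C,), descending
    patterns: np.ndarray            # (C, C) = inv(filters_w).T
    class_pair: str


def _trial_covariances(data: np.ndarray) -> np.ndarray:
    """Trace-normalized per-trial covariance matrices."""
    covs = np.einsum("ncl,nkl->nck", data, data)
    traces = np.trace(covs, axis1=1, axis2=2)
    return covs / traces[:, None, None]


def csp_from_covariances(S: np.ndarray, R: np.ndarray, class_pair: str = "injected") -> CSPResult:
    """CSP from explicit class covariance matrices (S vs R)."""
    try:
        lam, W = eigh(S, R)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "generalized eigendecomposition failed (singular covariance); "
            "increase the shrinkage regularization"
        ) from exc
    order = np.argsort(lam)[::-1]
    lam, W = lam[order], W[:, order]
    patterns = np.linalg.inv(W).T
    return CSPResult(filters_w=W, eigenvalues_lambda=lam, patterns=patterns,
                     class_pair=class_pair)


def csp_fit(dataset: EpochedDataset, class_a: int, class_b: int | None = None,
            regularization: float = 1e-6) -> CSPResult:
    """Fit CSP between ``class_a`` and ``class_b`` (or one-vs-rest if None).

    Covariances are per-trial, trace-normalized, averaged within class, with
    ``regularization * trace`` shrinkage added on the diagonal.  The input is
    expected to be band-limited already (see :func:`csp_importance`).
    """
    labels = dataset.labels
    mask_a = labels == class_a
    mask_b = (labels != class_a) if class_b is None else (labels == class_b)
    if not mask_a.any() or not mask_b.any():
        raise ValueError("both classes must be present in the dataset")
    C = dataset.n_channels
    S = _trial_covariances(dataset.data[mask_a]).mean(axis=0)
    R = _trial_covariances(dataset.data[mask_b]).mean(axis=0)
    S = S + regularization * np.trace(S) * np.eye(C)
    R = R + regularization * np.trace(R) * np.eye(C)
    pair = (f"one-vs-rest: class {class_a}" if class_b is None
            else f"class {class_a} vs class {class_b}")
    return csp_from_covariances(S, R, class_pair=pair)


def csp_pattern_activation(result: CSPResult, n_patterns: int = 5) -> ImportanceResult:
    """Channel importance from the first ``n_patterns`` spatial patterns.

    Pattern columns are normalized to unit L2 norm; the activation of a
    channel in a pattern is the absolute coefficient, and the per-channel
    score is the maximum activation over the first patterns.
    """
    C = result.patterns.shape[0]
    if n_patterns > C:
        raise ValueError(f"n_patterns={n_patterns} exceeds channel count {C}")
    cols = result.patterns[:, :n_patterns]
    cols = cols / np.linalg.norm(cols, axis=0, keepdims=True)
    activation = np.abs(cols)
    return ImportanceResult(
        method="csp_pattern",
        scores=activation.max(axis=1),
        metadata={"n_patterns": n_patterns, "class_pair": result.class_pair,
                  "activation": activation},
    )


def csp_importance(dataset: EpochedDataset, n_patterns: int = 5,
                   band: tuple[float, float] | None = (7.0, 35.0),
                   regularization: float = 1e-6) -> ImportanceResult:
    """CSP-pattern channel importance for two or more classes.

    The data are band-passed (default 7-35 Hz) first.  With two classes the
    contrast is fit directly; with more, one-vs-rest contrasts are fit per
    class, the resulting (eigenvalue, pattern) pairs are pooled and
    re-ranked by |log λ| — the symmetric distance from the no-contrast
    eigenvalue λ = 1, invariant to swapping the contrast's classes — and
    the first ``n_patterns`` pooled patterns score the channels.
    """
    if band is not None:
        dataset = bandpass_filter(dataset, *band)
    if dataset.n_classes == 2:
        result = csp_fit(dataset, 0, 1, regularization=regularization)
        return csp_pattern_activation(result, n_patterns=n_patterns)
    pooled_lam: list[float] = []
    pooled_patterns: list[np.ndarray] = []
    for k in range(dataset.n_classes):
        res = csp_fit(dataset, k, None, regularization=regularization)
        for j in range(res.patterns.shape[1]):
            pooled_lam.append(res.eigenvalues_lambda[j])
            pooled_patterns.append(res.patterns[:, j])
    order = np.argsort(-np.abs(np.log(np.asarray(pooled_lam))), kind="stable")
    cols = np.stack([pooled_patterns[i] for i in order[:n_patterns]], axis=1)
    cols = cols / np.linalg.norm(cols, axis=0, keepdims=True)
    activation = np.abs(cols)
    return ImportanceResult(
        method="csp_pattern",
        scores=activation.max(axis=1),
        metadata={"n_patterns": n_patterns, "class_pair": "one-vs-rest pooled",
                  "activation": activation},
    )


# ---------------------------------------------------------------------------
# wrapper methods
# ---------------------------------------------------------------------------

def permutation_importance(model, dataset: EpochedDataset, n_repeats: int = 10,
                           seed: int = 0) -> ImportanceResult:
    """Accuracy drop when one channel's trials are shuffled across trials.

    Whole trials of a single channel are re-assigned to other trials
    (waveforms intact, trial/label association broken).  The score of a
    channel is baseline accuracy minus the mean permuted accuracy over
    ``n_repeats`` shuffles.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    expected = getattr(model, "n_channels", None)
    if expected is not None and expected != dataset.n_channels:
        raise ValueError(
            f"model expects {expected} channels, dataset has {dataset.n_channels}"
        )
    rng = np.random.default_rng(seed)
    data, labels = dataset.data, dataset.labels
    baseline = float(np.mean(model.predict(data) == labels))
    n, C, _ = data.shape
    scores = np.zeros(C)
    for c in range(C):
        drops = []
        for _ in range(n_repeats):
            perm = rng.permutation(n)
            shuffled = data.copy()
            shuffled[:, c, :] = data[perm, c, :]
            acc = float(np.mean(model.predict(shuffled) == labels))
            drops.append(baseline - acc)
        scores[c] = np.mean(drops)
    return ImportanceResult(
        method="permutation",
        scores=scores,
        metadata={"baseline_accuracy": baseline, "n_repeats": n_repeats, "seed": seed},
    )


def random_search(dataset: EpochedDataset, subset_size: int = 6,
                  n_iterations: int = 500,
                  trainer: Callable[[EpochedDataset, int], float] | None = None,
                  seed: int = 0,
                  subsets: Sequence[Sequence[int]] | None = None) -> ImportanceResult:
    """Random channel-subset search.

    Each iteration draws ``subset_size`` distinct channels uniformly, trains
    and evaluates a classifier on that subset, and assigns the accuracy as
    the subset's weight.  A channel's score is the mean weight over the
    subsets containing it (its occurrence count is the denominator).
    Channels never drawn get a NaN score and a warning.  An explicit
    ``subsets`` list replaces the random draw (for reproducing a previous
    run or worked examples).
    """
    from .data_model import select_channels
    from .classifiers import band_power_trainer

    C = dataset.n_channels
    if subset_size > C:
        raise ValueError(f"subset_size={subset_size} exceeds channel count {C}")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    trainer = trainer or band_power_trainer
    rng = np.random.default_rng(seed)
    sums = np.zeros(C)
    counts = np.zeros(C, dtype=int)
    names = dataset.channel_names
    if subsets is not None:
        drawn = [np.asarray(sorted(s)) for s in subsets]
    else:
        drawn = [np.sort(rng.choice(C, size=subset_size, replace=False))
                 for _ in range(n_iterations)]
    for it, subset in enumerate(drawn):
        sub = select_channels(dataset, [names[i] for i in subset])
        weight = float(trainer(sub, seed + it))
        sums[subset] += weight
        counts[subset] += 1
    scores = np.full(C, np.nan)
    seen = counts > 0
    scores[seen] = sums[seen] / counts[seen]
    if not seen.all():
        missing = np.flatnonzero(~seen).tolist()
        warnings.warn(
            f"channels never selected in {n_iterations} iterations: {missing}; "
            "their scores are NaN", stacklevel=2,
        )
    return ImportanceResult(
        method="random_search",
        scores=scores,
        metadata={"subset_size": subset_size, "n_iterations": n_iterations,
                  "occurrences": counts, "seed": seed},
    )


def attention_experiment(dataset: EpochedDataset, n_models: int = 2,
                         epochs: int = 50, batch_size: int = 32,
                         filters_per_kernel: int = 8, seed: int = 0) -> ImportanceResult:
    """Channel importance from attention gates, stability-averaged.

    Trains up to ``n_models`` attention-augmented models from independent
    initializations/splits and combines their per-channel mean gate values,
    weighting each run by its peak test accuracy above chance.  A single
    run's gates reflect one local optimum — a gate can prune a channel
    whose information is partly redundant, and a run that barely learned
    carries little information about channel relevance — so gates are
    averaged across independent trainings in proportion to how well each
    model actually performed (runs at or below chance get zero weight; if
    all runs fail, plain averaging is used).  Training stops early once a
    replicate reaches twice chance accuracy: a skilled run dominates the
    weighted average, so extra replicates only matter when training fails.
    """
    from .data_model import SplitSpec
    from .neural_model import ModelConfig
    from .training_eval import TrainConfig, train_once

    gate_means = []
    peaks = []
    chance = 100.0 / dataset.n_classes
    skill_threshold = 2.0 * chance
    for m in range(n_models):
        run_seed = seed + 1000 * m
        config = ModelConfig(
            attention_enabled=True, filters_per_kernel=filters_per_kernel,
            dropout_rate=0.5,
        )
        result = train_once(
            dataset, config,
            TrainConfig(epochs=epochs, batch_size=batch_size, seed=run_seed,
                        eval_every=5),
            split=SplitSpec(seed=run_seed),
        )
        gates = result.model.attention_gates(result.normalize(dataset.data))
        gate_means.append(gates.mean(axis=0))
        peaks.append(result.peak_test_accuracy)
        # a skilled replicate is enough: its gates dominate the weighted
        # average anyway, so further replicates are only trained when every
        # run so far learned poorly
        if result.peak_test_accuracy >= skill_threshold:
            break
    weights = np.maximum(np.asarray(peaks) - chance, 0.0)
    if weights.sum() == 0:
        weights = np.ones(len(peaks))
    weights = weights / weights.sum()
    scores = np.einsum("m,mc->c", weights, np.stack(gate_means))
    return ImportanceResult(
        method="attention",
        scores=scores,
        metadata={"n_models": len(peaks), "epochs": epochs,
                  "peak_test_accuracies": peaks, "weights": weights, "seed": seed},
    )


def attention_importance(model, dataset: EpochedDataset) -> ImportanceResult:
    """Mean channel-attention gate value over all trials of the dataset."""
    gates_fn = getattr(model, "attention_gates", None)
    if gates_fn is None or not getattr(model, "attention_enabled", False):
        raise ValueError("model has no channel-attention front end")
    gates = gates_fn(dataset.data)  # (N, C)
    return ImportanceResult(
        method="attention",
        scores=gates.mean(axis=0),
        metadata={"n_trials": dataset.n_trials},
    )
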