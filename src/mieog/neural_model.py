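"""The multi-kernel 1-D depthwise-separable CNN with optional channel attention.

Architecture (time axis is the convolution axis; input is
``(batch, channels, samples)``):

1. optional channel-attention gate on the raw input channels,
2. three parallel temporal convolutions (kernels 3/5/9 by default, 32
   filters each, length-preserving padding) concatenated into 96 feature
   maps, then ReLU and batch normalization — activation-then-norm order,
   switchable,
3. a depthwise convolution (kernel 25, padding 7, one filter per map:
   output length L − 10),
4. a depthwise-separable convolution (same depthwise geometry + a pointwise
   1×1 mixing convolution, map count kept at 96),
5. batch normalization, ELU, average pooling, dropout, flatten, and a single
   dense layer to the class logits.

Everything runs on the small NumPy layer kernel in :mod:`mieog.nn`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    Adam,
    AvgPool1d,
    BatchNorm1d,
    ChannelAttention,
    Conv1d,
    Dense,
    Dropout,
    ELU,
    Flatten,
    ReLU,
    softmax_cross_entropy,
)

__all__ = ["ModelConfig", "ForwardTrace", "MultiKernelCNN", "build_model", "count_parameters"]


@dataclass
class ModelConfig:
    """Hyperparameters of the model; defaults follow the reference design."""

    n_channels: int = 25
    n_samples: int = 1000
    n_classes: int = 4
    temporal_kernels: tuple[int, ...] = (3, 5, 9)
    filters_per_kernel: int = 32
    depthwise_kernel: int = 25
    depthwise_padding: int = 7
    pool_size: int = 8
    dropout_rate: float = 0.5
    attention_enabled: bool = False
    attention_reduction: int = 4
    activation_before_norm: bool = True  # ReLU then BN after the temporal block
    depthwise_bias: bool = False

    @property
    def n_maps(self) -> int:
        """Concatenated temporal feature maps (96 for the default config)."""
        return self.filters_per_kernel * len(self.temporal_kernels)


@dataclass
class ForwardTrace:
    """Per-stage output shapes (maps, samples) and the final logit width."""

    stages: list[tuple[str, tuple[int, ...]]] = field(default_factory=list)

    def shape_of(self, stage: str) -> tuple[int, ...]:
        for name, shape in self.stages:
            if name == stage:
                return shape
        raise KeyError(stage)


def _same_padding(kernel: int) -> tuple[int, int]:
    """Length-preserving padding; asymmetric for even kernels."""
    return ((kernel - 1) // 2, kernel // 2)


class MultiKernelCNN:
    """Multi-kernel temporal CNN with depthwise-separable stages.

    Training runs in single precision by default (ample for SGD); pass
    ``dtype=np.float64`` where exact numerical checks matter.
    """

    def __init__(self, config: ModelConfig, seed: int = 0, dtype=np.float32):
        self.config = config
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(seed + 1)
        c = config

        self.attention = (
            ChannelAttention(c.n_channels, reduction=c.attention_reduction, rng=rng)
            if c.attention_enabled else None
        )
        self.temporal = [
            Conv1d(c.n_channels, c.filters_per_kernel, k, padding=_same_padding(k),
                   rng=rng, name=f"temporal_k{k}")
            for k in c.temporal_kernels
        ]
        maps = c.n_maps
        self.post_concat = [ReLU(), BatchNorm1d(maps, name="bn1")]
        if not c.activation_before_norm:
            self.post_concat.reverse()
        dw = dict(kernel_size=c.depthwise_kernel, padding=c.depthwise_padding,
                  groups=maps, bias=c.depthwise_bias, rng=rng)
        self.depthwise = Conv1d(maps, maps, name="depthwise", **dw)
        self.sep_depthwise = Conv1d(maps, maps, name="separable.depthwise", **dw)
        self.sep_pointwise = Conv1d(maps, maps, 1, rng=rng, name="separable.pointwise")
        self.head = [
            BatchNorm1d(maps, name="bn2"),
            ELU(),
            AvgPool1d(c.pool_size),
            Dropout(c.dropout_rate, self._dropout_rng),
            Flatten(),
        ]
        trace = self.forward_trace()
        n_features = int(np.prod(trace.shape_of("flatten")))
        self.dense = Dense(n_features, c.n_classes, rng=rng)
        for p in self.params():
            p.value = p.value.astype(self.dtype)
            p.grad = p.grad.astype(self.dtype)
        for layer in self._all_layers():
            if isinstance(layer, BatchNorm1d):
                layer.running_mean = layer.running_mean.astype(self.dtype)
                layer.running_var = layer.running_var.astype(self.dtype)

    def _all_layers(self):
        return ([self.attention] if self.attention else []) + self.temporal \
            + self.post_concat + [self.depthwise, self.sep_depthwise,
                                  self.sep_pointwise] + self.head + [self.dense]

    # -- plumbing ----------------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.config.n_channels

    @property
    def attention_enabled(self) -> bool:
        return self.attention is not None

    def params(self):
        return [p for layer in self._all_layers() for p in layer.params()]

    def forward_trace(self) -> ForwardTrace:
        """Analytic per-stage shapes for the configured input length."""
        c = self.config
        L = c.n_samples
        trace = ForwardTrace()
        if self.attention:
            trace.stages.append(("attention", (c.n_channels, L)))
        trace.stages.append(("temporal_concat", (c.n_maps, L)))
        L1 = self.depthwise.out_length(L)
        if L1 < 1:
            raise ValueError(f"input length {L} too short for the depthwise stage")
        trace.stages.append(("depthwise", (c.n_maps, L1)))
        L2 = self.sep_depthwise.out_length(L1)
        if L2 < 1:
            raise ValueError(f"length {L1} too short for the separable stage")
        trace.stages.append(("separable", (c.n_maps, L2)))
        L3 = L2 // c.pool_size
        if L3 < 1:
            raise ValueError(f"length {L2} too short for pooling by {c.pool_size}")
        trace.stages.append(("pool", (c.n_maps, L3)))
        trace.stages.append(("flatten", (c.n_maps * L3,)))
        trace.stages.append(("logits", (c.n_classes,)))
        return trace

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        self._seq = []

        def run(layer, z):
            out = layer.forward(z, training)
            self._seq.append(layer)
            return out

        if self.attention:
            x = run(self.attention, x)
        branch_outs = [run(conv, x) for conv in self.temporal]
        self._n_branches = len(branch_outs)
        z = np.concatenate(branch_outs, axis=1)
        for layer in self.post_concat:
            z = run(layer, z)
        z = run(self.depthwise, z)
        z = run(self.sep_depthwise, z)
        z = run(self.sep_pointwise, z)
        for layer in self.head:
            z = run(layer, z)
        return run(self.dense, z)

    def backward(self, grad: np.ndarray) -> None:
        grad = np.asarray(grad, dtype=self.dtype)
        seq = list(self._seq)
        # walk back to the concatenation point
        n_branch = self._n_branches
        split_at = (1 if self.attention else 0) + n_branch
        tail, branches = seq[split_at:], seq[split_at - n_branch:split_at]
        for layer in reversed(tail):
            grad = layer.backward(grad)
        f = self.config.filters_per_kernel
        chunks = [grad[:, i * f:(i + 1) * f, :] for i in range(n_branch)]
        dx = sum(conv.backward(chunk) for conv, chunk in zip(branches, chunks))
        if self.attention:
            self.attention.backward(dx)

    # -- inference helpers -------------------------------------------------
    def predict(self, data: np.ndarray, batch_size: int = 256) -> np.ndarray:
        preds = []
        for i in range(0, data.shape[0], batch_size):
            logits = self.forward(data[i:i + batch_size], training=False)
            preds.append(logits.argmax(axis=1))
        return np.concatenate(preds)

    def attention_gates(self, data: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Per-trial attention gate values, shape (n_trials, n_channels)."""
        if not self.attention:
            raise ValueError("model has no channel-attention front end")
        gates = []
        for i in range(0, data.shape[0], batch_size):
            self.attention.forward(data[i:i + batch_size], training=False)
            gates.append(self.attention.last_gates)
        return np.concatenate(gates)

    def attention_forward(self, data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Apply only the attention gate: (gated batch, gates)."""
        if not self.attention:
            raise ValueError("model has no channel-attention front end")
        gated = self.attention.forward(data, training=False)
        return gated, self.attention.last_gates


def build_model(config: ModelConfig, seed: int = 0) -> MultiKernelCNN:
    """Construct the model; raises if ``n_samples`` is too short for a stage."""
    return MultiKernelCNN(config, seed=seed)


def count_parameters(model: MultiKernelCNN) -> int:
    """Total number of trainable scalar parameters."""
    return int(sum(p.value.size for p in model.params()))
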