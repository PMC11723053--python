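"""1-D convolutional layers with explicit forward/backward passes.

Shapes follow the (batch, channels, samples) convention throughout.  Each
layer caches what its backward pass needs; ``backward`` consumes the
gradient w.r.t. its output and returns the gradient w.r.t. its input while
accumulating parameter gradients in :class:`Param` objects.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param", "Layer", "Conv1d", "BatchNorm1d", "ReLU", "ELU", "AvgPool1d",
    "Dropout", "Flatten", "Dense", "ChannelAttention",
]


class Param:
    """A trainable tensor and its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class Conv1d(Layer):
    """Grouped 1-D convolution (cross-correlation), optional asymmetric padding.

    ``groups == in_channels == out_channels`` gives a depthwise convolution
    (one filter per input map, C·K weights instead of C²·K).
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 padding: int | tuple[int, int] = 0, groups: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None,
                 name: str = "conv"):
        if in_channels % groups or out_channels % groups:
            raise ValueError("channel counts must be divisible by groups")
        rng = rng or np.random.default_rng(0)
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel_size, self.groups = kernel_size, groups
        self.padding = (padding, padding) if isinstance(padding, int) else tuple(padding)
        cg = in_channels // groups
        self.W = Param(_he_init(rng, (out_channels, cg, kernel_size), cg * kernel_size),
                       name=f"{name}.W")
        self.b = Param(np.zeros(out_channels), name=f"{name}.b") if bias else None
        self.name = name

    def out_length(self, L: int) -> int:
        return L + sum(self.padding) - self.kernel_size + 1

    def params(self) -> list[Param]:
        return [self.W] + ([self.b] if self.b is not None else [])

    @property
    def _depthwise(self) -> bool:
        return self.groups == self.in_channels == self.out_channels

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        N, C, L = x.shape
        Lo = self.out_length(L)
        if Lo < 1:
            raise ValueError(
                f"layer {self.name}: input length {L} too short for kernel "
                f"{self.kernel_size} with padding {self.padding}"
            )
        k = self.kernel_size
        if k == 1 and self.groups == 1 and self.padding == (0, 0):
            # pointwise: a channel-mixing matmul
            out = np.einsum("oc,ncl->nol", self.W.value[:, :, 0], x, optimize=True)
            self._cache = x
        elif self.groups == 1:
            xp = np.pad(x, ((0, 0), (0, 0), self.padding))
            win = sliding_window_view(xp, k, axis=2)  # N,C,Lo,k
            out = np.einsum("nclk,ock->nol", win, self.W.value, optimize=True)
            self._cache = win
        elif self._depthwise:
            xp = np.pad(x, ((0, 0), (0, 0), self.padding))
            win = sliding_window_view(xp, k, axis=2)
            out = np.einsum("nclk,ck->ncl", win, self.W.value[:, 0, :], optimize=True)
            self._cache = win
        else:
            xp = np.pad(x, ((0, 0), (0, 0), self.padding))
            win = sliding_window_view(xp, k, axis=2)
            g, cg = self.groups, C // self.groups
            og = self.out_channels // self.groups
            wing = win.reshape(N, g, cg, Lo, k)
            Wg = self.W.value.reshape(g, og, cg, k)
            out = np.einsum("ngclk,gock->ngol", wing, Wg, optimize=True)
            out = out.reshape(N, self.out_channels, Lo)
            self._cache = wing
        self._nlo = (N, Lo)
        if self.b is not None:
            out += self.b.value[None, :, None]
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        N, Lo = self._nlo
        k = self.kernel_size
        O, C = self.out_channels, self.in_channels
        lpad, rpad = self.padding
        if self.b is not None:
            self.b.grad += grad.sum(axis=(0, 2))
        if k == 1 and self.groups == 1 and self.padding == (0, 0):
            x = self._cache
            self.W.grad[:, :, 0] += np.einsum("nol,ncl->oc", grad, x, optimize=True)
            return np.einsum("oc,nol->ncl", self.W.value[:, :, 0], grad, optimize=True)
        if self.groups == 1:
            win = self._cache
            self.W.grad += np.einsum("nclk,nol->ock", win, grad, optimize=True)
            gp = np.pad(grad, ((0, 0), (0, 0), (k - 1 - lpad, k - 1 - rpad)))
            gwin = sliding_window_view(gp, k, axis=2)  # N,O,Lin,k
            return np.einsum("nolk,ock->ncl", gwin, self.W.value[:, :, ::-1],
                             optimize=True)
        if self._depthwise:
            win = self._cache
            self.W.grad[:, 0, :] += np.einsum("nclk,ncl->ck", win, grad, optimize=True)
            gp = np.pad(grad, ((0, 0), (0, 0), (k - 1 - lpad, k - 1 - rpad)))
            gwin = sliding_window_view(gp, k, axis=2)  # N,C,Lin,k
            return np.einsum("nclk,ck->ncl", gwin, self.W.value[:, 0, ::-1],
                             optimize=True)
        wing = self._cache
        g, og, cg = self.groups, O // self.groups, C // self.groups
        gradg = grad.reshape(N, g, og, Lo)
        Wg = self.W.value.reshape(g, og, cg, k)
        dW = np.einsum("ngclk,ngol->gock", wing, gradg, optimize=True)
        self.W.grad += dW.reshape(self.W.value.shape)
        gp = np.pad(gradg, ((0, 0), (0, 0), (0, 0), (k - 1 - lpad, k - 1 - rpad)))
        gwin = sliding_window_view(gp, k, axis=3)
        dx = np.einsum("ngolk,gock->ngcl", gwin, Wg[..., ::-1], optimize=True)
        return dx.reshape(N, C, -1)


class BatchNorm1d(Layer):
    """Per-feature-map batch normalization over (batch, time)."""

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = "bn"):
        self.gamma = Param(np.ones(num_features), name=f"{name}.gamma")
        self.beta = Param(np.zeros(num_features), name=f"{name}.beta")
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self.momentum, self.eps = momentum, eps

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_sd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv_sd[None, :, None]
        self._cache = (xhat, inv_sd, training, x.shape)
        return self.gamma.value[None, :, None] * xhat + self.beta.value[None, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_sd, training, shape = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2))
        self.beta.grad += grad.sum(axis=(0, 2))
        gscaled = grad * self.gamma.value[None, :, None]
        if not training:
            return gscaled * inv_sd[None, :, None]
        m = shape[0] * shape[2]
        return (inv_sd[None, :, None] / m) * (
            m * gscaled
            - gscaled.sum(axis=(0, 2), keepdims=True)
            - xhat * (gscaled * xhat).sum(axis=(0, 2), keepdims=True)
        )


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def forward(self, x, training):
        neg = x <= 0
        out = np.where(neg, self.alpha * np.expm1(x), x)
        self._cache = (neg, out)
        return out

    def backward(self, grad):
        neg, out = self._cache
        return grad * np.where(neg, out + self.alpha, 1.0)


class AvgPool1d(Layer):
    """Non-overlapping average pooling; trailing remainder samples dropped."""

    def __init__(self, pool_size: int):
        if pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        self.pool_size = pool_size

    def out_length(self, L: int) -> int:
        return L // self.pool_size

    def forward(self, x, training):
        N, C, L = x.shape
        Lo = self.out_length(L)
        if Lo < 1:
            raise ValueError(f"average pooling: input length {L} < pool {self.pool_size}")
        self._in_len = L
        return x[:, :, :Lo * self.pool_size].reshape(N, C, Lo, self.pool_size).mean(axis=3)

    def backward(self, grad):
        N, C, Lo = grad.shape
        dx = np.zeros((N, C, self._in_len), dtype=grad.dtype)
        dx[:, :, :Lo * self.pool_size] = np.repeat(grad / self.pool_size, self.pool_size, axis=2)
        return dx


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate, self.rng = rate, rng

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = ((self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)).astype(x.dtype)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None, name: str = "dense"):
        rng = rng or np.random.default_rng(0)
        self.W = Param(_he_init(rng, (out_features, in_features), in_features),
                       name=f"{name}.W")
        self.b = Param(np.zeros(out_features), name=f"{name}.b")

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training):
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, grad):
        self.W.grad += grad.T @ self._x
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class ChannelAttention(Layer):
    """Per-channel multiplicative gate from pooled channel statistics.

    Adaptive average- and max-pooling collapse the time axis; both pooled
    vectors pass through a shared bottleneck (pointwise conv C -> ceil(C/r),
    ReLU, pointwise conv back to C); the two paths are summed and
    sigmoid-squashed into gates in (0, 1) that scale the input per channel.
    """

    def __init__(self, n_channels: int, reduction: int = 4,
                 rng: np.random.Generator | None = None, name: str = "attention"):
        if reduction < 1:
            raise ValueError("reduction must be >= 1")
        rng = rng or np.random.default_rng(0)
        hidden = max(1, int(np.ceil(n_channels / reduction)))
        self.n_channels, self.hidden = n_channels, hidden
        self.W1 = Param(_he_init(rng, (hidden, n_channels), n_channels), name=f"{name}.W1")
        self.b1 = Param(np.zeros(hidden), name=f"{name}.b1")
        # restoring conv starts at zero so gates begin at sigmoid(0) = 0.5:
        # a neutral gate; anything hotter saturates the sigmoid at init and
        # silences random channels before training starts
        self.W2 = Param(np.zeros((n_channels, hidden)), name=f"{name}.W2")
        self.b2 = Param(np.zeros(n_channels), name=f"{name}.b2")
        self.last_gates: np.ndarray | None = None

    def params(self):
        return [self.W1, self.b1, self.W2, self.b2]

    def _mlp(self, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        z = v @ self.W1.value.T + self.b1.value
        h = np.maximum(z, 0.0)
        return h @ self.W2.value.T + self.b2.value, h

    def forward(self, x, training):
        a = x.mean(axis=2)                       # N,C
        m = x.max(axis=2)
        argm = x.argmax(axis=2)
        sa, ha = self._mlp(a)
        sm, hm = self._mlp(m)
        gate = _sigmoid(sa + sm)
        self.last_gates = gate
        self._cache = (x, a, m, argm, ha, hm, gate)
        return x * gate[:, :, None]

    def _mlp_backward(self, ds: np.ndarray, v: np.ndarray, h: np.ndarray) -> np.ndarray:
        self.W2.grad += ds.T @ h
        self.b2.grad += ds.sum(axis=0)
        dh = (ds @ self.W2.value) * (h > 0)
        self.W1.grad += dh.T @ v
        self.b1.grad += dh.sum(axis=0)
        return dh @ self.W1.value

    def backward(self, grad):
        x, a, m, argm, ha, hm, gate = self._cache
        N, C, L = x.shape
        dgate = (grad * x).sum(axis=2)
        dx = grad * gate[:, :, None]
        ds = dgate * gate * (1.0 - gate)
        da = self._mlp_backward(ds, a, ha)
        dm = self._mlp_backward(ds, m, hm)
        dx += da[:, :, None] / L
        n_idx, c_idx = np.meshgrid(np.arange(N), np.arange(C), indexing="ij")
        dx[n_idx, c_idx, argm] += dm
        return dx
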