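"""Neural-network layers on top of the autograd tape.

Layers hold their parameters as ``Tensor(requires_grad=True)`` attributes and
are called as ``layer(x, train=bool)``. Randomness (weight init, dropout,
stochastic depth) comes exclusively from injected ``numpy.random.Generator``
instances — there is no global RNG state, so a seeded model is reproducible.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = [
    "Layer",
    "Sequential",
    "Conv3d",
    "ConvTranspose3d",
    "DepthwiseConv3d",
    "BatchNorm",
    "GroupNorm",
    "PReLU",
    "Swish",
    "Sigmoid",
    "Dropout",
    "Dense",
    "SqueezeExcite",
]


class Layer:
    """Base class: recursive parameter collection and train/eval dispatch."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()

        def collect(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Layer):
                for v in vars(obj).values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)

        collect(self)
        return params

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        raise NotImplementedError


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        for layer in self.layers:
            x = layer(x, train=train)
        return x


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    scale = np.sqrt(2.0 / max(fan_in, 1))
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


class Conv3d(Layer):
    """'same'-padded 3D convolution. 2D slice-wise convs use kernel (k, k, 1)."""

    def __init__(self, in_ch: int, out_ch: int, kernel=(3, 3, 3), stride=(1, 1, 1), *,
                 rng: np.random.Generator, bias: bool = True):
        kernel = tuple(kernel)
        self.stride = tuple(stride)
        fan_in = in_ch * int(np.prod(kernel))
        self.weight = _he_init(rng, (out_ch, in_ch, *kernel), fan_in)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        return x.conv3d(self.weight, self.bias, stride=self.stride)


class DepthwiseConv3d(Layer):
    def __init__(self, ch: int, kernel=(3, 3, 3), stride=(1, 1, 1), *,
                 rng: np.random.Generator, bias: bool = True):
        kernel = tuple(kernel)
        self.stride = tuple(stride)
        self.weight = _he_init(rng, (ch, *kernel), int(np.prod(kernel)))
        self.bias = Tensor(np.zeros(ch), requires_grad=True) if bias else None

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        return x.depthwise_conv3d(self.weight, self.bias, stride=self.stride)


class ConvTranspose3d(Layer):
    """Upsampling transposed convolution with kernel equal to stride."""

    def __init__(self, in_ch: int, out_ch: int, stride=(2, 2, 2), *, rng: np.random.Generator):
        self.stride = tuple(stride)
        fan_in = in_ch * int(np.prod(self.stride))
        self.weight = _he_init(rng, (in_ch, out_ch, *self.stride), fan_in)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        return x.conv_transpose3d(self.weight, self.bias, stride=self.stride)


class BatchNorm(Layer):
    """Normalization over batch and spatial axes per channel.

    Uses batch statistics in training (batch size 2 in the reference recipe)
    and running averages at inference.
    """

    def __init__(self, ch: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(ch), requires_grad=True)
        self.beta = Tensor(np.zeros(ch), requires_grad=True)
        self.running_mean = np.zeros(ch)
        self.running_var = np.ones(ch)
        self.momentum = momentum
        self.eps = eps

    def _bshape(self, x: Tensor):
        return (1, -1) + (1,) * (x.ndim - 2)

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        axes = (0,) + tuple(range(2, x.ndim))
        shape = self._bshape(x)
        if train:
            mu = x.mean(axis=axes, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=axes, keepdims=True)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mu.data.reshape(-1)
            )
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var.data.reshape(-1)
            )
            xhat = xc / (var + self.eps).sqrt()
        else:
            mu = self.running_mean.reshape(shape)
            sd = np.sqrt(self.running_var.reshape(shape) + self.eps)
            xhat = (x - mu) * (1.0 / sd)
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class GroupNorm(Layer):
    """Group normalization fallback for batch-size-1 desk runs."""

    def __init__(self, ch: int, groups: int = 1, eps: float = 1e-5):
        if ch % groups:
            raise ValueError("channels must divide into groups")
        self.gamma = Tensor(np.ones(ch), requires_grad=True)
        self.beta = Tensor(np.zeros(ch), requires_grad=True)
        self.groups = groups
        self.eps = eps

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        N, C = x.shape[:2]
        spatial = x.shape[2:]
        g = self.groups
        xg = x.reshape(N, g, C // g, *spatial)
        axes = tuple(range(2, xg.ndim))
        mu = xg.mean(axis=axes, keepdims=True)
        xc = xg - mu
        var = (xc * xc).mean(axis=axes, keepdims=True)
        xhat = (xc / (var + self.eps).sqrt()).reshape(N, C, *spatial)
        shape = (1, C) + (1,) * len(spatial)
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class PReLU(Layer):
    """Parametric ReLU with one learnable slope per channel."""

    def __init__(self, ch: int, init: float = 0.25):
        self.alpha = Tensor(np.full(ch, init), requires_grad=True)

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        shape = (1, -1) + (1,) * (x.ndim - 2)
        return x.relu() - self.alpha.reshape(shape) * (-x).relu()


class Swish(Layer):
    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        return x.swish()


class Sigmoid(Layer):
    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        return x.sigmoid()


class Dropout(Layer):
    """Element-wise ('non-spatial') inverted dropout."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        if not train or self.rate == 0:
            return x
        keep = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * Tensor(keep)


class StochasticDepth(Layer):
    """Drops a whole residual branch with probability ``rate`` during training."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        if not train or self.rate == 0:
            return x
        if self.rng.random() < self.rate:
            return x * 0.0
        return x * (1.0 / (1.0 - self.rate))


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, *, rng: np.random.Generator):
        self.weight = _he_init(rng, (in_features, out_features), in_features)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        return x @ self.weight + self.bias


class SqueezeExcite(Layer):
    """Channel gating: global average pool, squeeze (swish), excite (sigmoid)."""

    def __init__(self, ch: int, ratio: float = 0.25, *, rng: np.random.Generator):
        hidden = max(1, int(round(ch * ratio)))
        self.squeeze = Conv3d(ch, hidden, kernel=(1, 1, 1), rng=rng)
        self.excite = Conv3d(hidden, ch, kernel=(1, 1, 1), rng=rng)

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        pooled = x.mean(axis=(2, 3, 4), keepdims=True)
        gate = self.excite(self.squeeze(pooled).swish()).sigmoid()
        return x * gate
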