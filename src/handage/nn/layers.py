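"""Neural-network layers built on the :mod:`handage.nn.tensor` autodiff core.

Layer parameters are :class:`Tensor` objects with ``requires_grad=True``,
initialized from an explicit ``numpy.random.Generator`` so that every network
in the package is reproducible from a single seed.  Convolutions use
fan-in-scaled ("He") normal initialization; biases start at zero.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = [
    "Module", "Sequential", "Conv2d", "DepthwiseConv2d", "BatchNorm2d",
    "Linear", "ReLU", "HSwish", "HSigmoid", "Identity", "GlobalAvgPool2d",
    "SqueezeExcite", "InvertedResidual", "make_divisible",
]


class Module:
    """Minimal module base: parameter discovery, train/eval mode."""

    def __init__(self):
        self.training = True

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def children(self):
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def parameters(self):
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                yield value
        for child in self.children():
            yield from child.parameters()

    def named_parameters(self, prefix: str = ""):
        for name, value in self.__dict__.items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield f"{prefix}{name}", value
        for name, value in self.__dict__.items():
            if isinstance(value, Module):
                yield from value.named_parameters(f"{prefix}{name}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")

    def buffers(self):
        """Named non-learnable state (batch-norm running statistics)."""
        for name, value in self.__dict__.items():
            if isinstance(value, np.ndarray):
                yield name, value
        for name, value in self.__dict__.items():
            if isinstance(value, Module):
                for sub, arr in value.buffers():
                    yield f"{name}.{sub}", arr
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        for sub, arr in item.buffers():
                            yield f"{name}.{i}.{sub}", arr

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        self.training = mode
        for child in self.children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- flat (de)serialization -------------------------------------------
    def state_dict(self) -> dict:
        state = {f"param.{k}": v.data for k, v in self.named_parameters()}
        state.update({f"buffer.{k}": v for k, v in self.buffers()})
        return state

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        for key, arr in state.items():
            kind, _, name = key.partition(".")
            if kind != "param":
                continue
            if name not in params:
                raise KeyError(f"unknown parameter {name!r} in state")
            if params[name].data.shape != arr.shape:
                raise ValueError(f"shape mismatch for {name!r}: "
                                 f"{params[name].data.shape} vs {arr.shape}")
            params[name].data = arr.astype(params[name].data.dtype)
        for key, arr in state.items():
            kind, _, name = key.partition(".")
            if kind != "buffer":
                continue
            obj = self
            parts = name.split(".")
            for part in parts[:-1]:
                obj = obj[int(part)] if part.isdigit() else obj.__dict__[part]
            setattr(obj, parts[-1], arr.copy())


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, bias: bool = False,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(rng.normal(0.0, std, (out_channels, in_channels,
                                                   kernel_size, kernel_size)).astype(dtype),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=dtype), requires_grad=True) if bias else None
        self.stride, self.padding = stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride, padding=self.padding)


class DepthwiseConv2d(Module):
    """One spatial filter per input channel (channel multiplier 1)."""

    def __init__(self, channels: int, kernel_size: int, stride: int = 1,
                 padding: int = 0, bias: bool = False,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / (kernel_size * kernel_size))
        self.weight = Tensor(rng.normal(0.0, std, (channels, kernel_size, kernel_size)).astype(dtype),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True) if bias else None
        self.stride, self.padding = stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return x.depthwise_conv2d(self.weight, self.bias, stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    """Per-channel normalization; batch statistics in train mode, running
    statistics in eval mode.  Running stats are buffers, not parameters."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1, dtype=np.float32):
        super().__init__()
        self.gamma = Tensor(np.ones(channels, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.eps, self.momentum = eps, momentum

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            axes = (0,) + tuple(range(2, x.data.ndim))
            mean = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(self.running_mean.dtype)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(self.running_var.dtype)
            return x.batch_norm(self.gamma, self.beta, eps=self.eps)
        return x.batch_norm(self.gamma, self.beta, eps=self.eps,
                            mean=self.running_mean, var=self.running_var)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / in_features)
        self.weight = Tensor(rng.normal(0.0, std, (in_features, out_features)).astype(dtype),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, dtype=dtype), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        return out + self.bias if self.bias is not None else out


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class HSwish(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.hswish()


class HSigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.hsigmoid()


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class GlobalAvgPool2d(Module):
    """Adaptive average pooling to 1x1, returned as (N, C)."""

    def forward(self, x: Tensor) -> Tensor:
        return x.mean(axis=(2, 3))


def make_divisible(v: float, divisor: int = 8) -> int:
    """Round channel counts to multiples of ``divisor``, never below 90% of v."""
    new_v = max(divisor, int(v + divisor / 2) // divisor * divisor)
    if new_v < 0.9 * v:
        new_v += divisor
    return new_v


class SqueezeExcite(Module):
    """Squeeze (global average pool) -> FC bottleneck (ReLU) -> FC -> hard
    sigmoid gate -> per-channel rescale.  Gates lie in (0, 1], so the block
    never amplifies a channel."""

    def __init__(self, channels: int, squeeze_channels: int | None = None,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        squeeze_channels = squeeze_channels or make_divisible(channels // 4)
        self.fc1 = Linear(channels, squeeze_channels, rng=rng, dtype=dtype)
        self.fc2 = Linear(squeeze_channels, channels, rng=rng, dtype=dtype)

    def squeeze(self, x: Tensor) -> Tensor:
        return x.mean(axis=(2, 3))

    def forward(self, x: Tensor) -> Tensor:
        s = self.squeeze(x)
        s = self.fc1(s).relu()
        gate = self.fc2(s).hsigmoid()
        n, c = gate.shape
        return x * gate.reshape(n, c, 1, 1)


def _nonlinearity(name: str) -> Module:
    return {"HS": HSwish(), "RE": ReLU(), "-": Identity()}[name]


class InvertedResidual(Module):
    """Expand (1x1) -> depthwise (k x k, stride s) -> optional SE -> project
    (1x1, linear).  The skip connection is applied iff stride == 1 and the
    input/output channel counts match.  The expansion stage is omitted when
    the expanded width equals the input width (first block)."""

    def __init__(self, in_channels: int, expanded: int, out_channels: int,
                 kernel_size: int, stride: int, use_se: bool, nl: str,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        if stride not in (1, 2):
            raise ValueError(f"stride must be 1 or 2, got {stride}")
        self.use_skip = stride == 1 and in_channels == out_channels
        self.expand = None
        if expanded != in_channels:
            self.expand = Sequential(
                Conv2d(in_channels, expanded, 1, rng=rng, dtype=dtype),
                BatchNorm2d(expanded, dtype=dtype), _nonlinearity(nl))
        self.depthwise = Sequential(
            DepthwiseConv2d(expanded, kernel_size, stride=stride,
                            padding=(kernel_size - 1) // 2, rng=rng, dtype=dtype),
            BatchNorm2d(expanded, dtype=dtype), _nonlinearity(nl))
        self.se = SqueezeExcite(expanded, rng=rng, dtype=dtype) if use_se else None
        self.project = Sequential(
            Conv2d(expanded, out_channels, 1, rng=rng, dtype=dtype),
            BatchNorm2d(out_channels, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        out = x
        if self.expand is not None:
            out = self.expand(out)
        out = self.depthwise(out)
        if self.se is not None:
            out = self.se(out)
        out = self.project(out)
        return out + x if self.use_skip else out
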