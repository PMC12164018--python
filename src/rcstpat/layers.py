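"""Neural-network building blocks on top of the autodiff core.

Feature maps are (C, H, W) float64 tensors (single sample — the training
protocol uses batch size 1).  All parameter initialization draws from an
explicit ``numpy.random.Generator`` passed in at construction, in a fixed
order, so a model built twice from the same seed has an identical parameter
vector.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv2d

__all__ = [
    "Module",
    "Conv2d",
    "ChannelLayerNorm",
    "pixel_unshuffle",
    "pixel_shuffle",
    "RMSprop",
]


class Module:
    """Base class: tracks parameters and sub-modules by attribute assignment."""

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        elif isinstance(value, (list, tuple)) and value and all(
            isinstance(v, Module) for v in value
        ):
            for i, v in enumerate(value):
                self.__dict__.setdefault("_children", {})[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, p in self.__dict__.get("_params", {}).items():
            out[prefix + name] = p
        for name, child in self.__dict__.get("_children", {}).items():
            out.update(child.named_parameters(prefix + name + "."))
        return out

    def parameters(self) -> list[Tensor]:
        return list(self.named_parameters().values())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_vector(self) -> np.ndarray:
        """All parameters flattened into one vector (fixed traversal order)."""
        params = self.named_parameters()
        if not params:
            return np.zeros(0)
        return np.concatenate([params[k].data.ravel() for k in sorted(params)])

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"parameter name mismatch: {sorted(missing)}")
        for name, p in params.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.asarray(state[name], dtype=np.float64).copy()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}


class Conv2d(Module):
    """2-D convolution layer; He-normal weight init, zero bias."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int | None = None,
        groups: int = 1,
        bias: bool = True,
        init: str = "he",
    ):
        self.stride = stride
        self.groups = groups
        self.padding = kernel_size // 2 if padding is None else padding
        fan_in = (in_channels // groups) * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)
        shape = (out_channels, in_channels // groups, kernel_size, kernel_size)
        if init == "zero":
            w = np.zeros(shape)
        else:
            w = rng.normal(0.0, std, size=shape)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(
            x, self.weight, self.bias, stride=self.stride, padding=self.padding,
            groups=self.groups,
        )


class ChannelLayerNorm(Module):
    """Bias-free layer normalization across channels at each spatial site."""

    def __init__(self, channels: int, eps: float = 1e-6):
        self.eps = eps
        self.gamma = Tensor(np.ones((channels, 1, 1)), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=0, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=0, keepdims=True)
        return self.gamma * (xc / (var + self.eps).sqrt())


def pixel_unshuffle(x: Tensor, r: int = 2) -> Tensor:
    """(C, H, W) -> (C*r^2, H/r, W/r); rearrangement only, no mixing."""
    C, H, W = x.shape
    if H % r or W % r:
        raise ValueError(f"spatial dims ({H}, {W}) not divisible by {r}")
    return (
        x.reshape(C, H // r, r, W // r, r)
        .transpose(0, 2, 4, 1, 3)
        .reshape(C * r * r, H // r, W // r)
    )


def pixel_shuffle(x: Tensor, r: int = 2) -> Tensor:
    """(C*r^2, H, W) -> (C, H*r, W*r); exact inverse of pixel_unshuffle."""
    C, H, W = x.shape
    if C % (r * r):
        raise ValueError(f"channel dim {C} not divisible by {r * r}")
    return (
        x.reshape(C // (r * r), r, r, H, W)
        .transpose(0, 3, 1, 4, 2)
        .reshape(C // (r * r), H * r, W * r)
    )


class RMSprop:
    """RMSprop with the standard running mean of squared gradients and an
    optional heavy-ball momentum buffer.

    sq <- alpha * sq + (1 - alpha) * g^2
    buf <- momentum * buf + g / (sqrt(sq) + eps)
    p  <- p - lr * buf
    """

    def __init__(self, params: list[Tensor], lr: float = 1e-4, alpha: float = 0.99,
                 eps: float = 1e-8, momentum: float = 0.0):
        self.params = list(params)
        self.lr = float(lr)
        self.alpha = float(alpha)
        self.eps = float(eps)
        self.momentum = float(momentum)
        self.sq = [np.zeros_like(p.data) for p in self.params]
        self.buf = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, sq, buf in zip(self.params, self.sq, self.buf):
            if p.grad is None:
                continue
            g = p.grad
            sq *= self.alpha
            sq += (1.0 - self.alpha) * g * g
            upd = g / (np.sqrt(sq) + self.eps)
            if self.momentum > 0.0:
                buf *= self.momentum
                buf += upd
                upd = buf
            p.data -= self.lr * upd

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
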