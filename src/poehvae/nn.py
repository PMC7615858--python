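"""Network building blocks: modules, convolutional cells, and Adam.

Layers follow the NVAE/MobileNetV2 recipe named in the architecture design:
depthwise-separable inverted-residual cells with squeeze-and-excitation gating
and Swish activations. Normalisation layers are omitted; weights use He/Glorot
fan-in scaling so the desk-scale networks train stably without them.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from .autodiff import Tensor, conv2d, depthwise_conv2d

__all__ = [
    "Module",
    "Conv2d",
    "DepthwiseConv2d",
    "SqueezeExcite",
    "InvertedResidualCell",
    "ResNetBlock",
    "PatchDiscriminator",
    "Adam",
]


class Module:
    """Base class with recursive parameter registration via attributes."""

    def __init__(self):
        self._params: "OrderedDict[str, Tensor]" = OrderedDict()
        self._modules: "OrderedDict[str, Module]" = OrderedDict()

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", OrderedDict())[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", OrderedDict())[name] = value
        elif isinstance(value, (list, tuple)) and value and all(isinstance(v, Module) for v in value):
            mods = self.__dict__.setdefault("_modules", OrderedDict())
            for i, v in enumerate(value):
                mods[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise KeyError(f"state dict mismatch: {sorted(missing)[:5]} ...")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = arr.copy()

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None


def _he(rng: np.random.Generator, shape, fan_in: int, dtype=np.float32) -> Tensor:
    std = np.sqrt(2.0 / max(fan_in, 1))
    return Tensor(rng.normal(0.0, std, size=shape).astype(dtype), requires_grad=True)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int | None = None, zero_init: bool = False):
        super().__init__()
        if padding is None:
            padding = kernel // 2
        self.stride, self.padding = stride, padding
        if zero_init:
            self.w = Tensor(np.zeros((cout, cin, kernel, kernel), np.float32), requires_grad=True)
        else:
            self.w = _he(rng, (cout, cin, kernel, kernel), cin * kernel * kernel)
        self.b = Tensor(np.zeros(cout, np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, padding=self.padding)


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1):
        super().__init__()
        self.stride, self.padding = stride, kernel // 2
        self.w = _he(rng, (channels, kernel, kernel), kernel * kernel)

    def __call__(self, x: Tensor) -> Tensor:
        return depthwise_conv2d(x, self.w, stride=self.stride, padding=self.padding)


class SqueezeExcite(Module):
    """Channel gating: global pool -> bottleneck -> sigmoid scale."""

    def __init__(self, channels: int, rng: np.random.Generator, reduction: int = 16):
        super().__init__()
        hidden = max(channels // reduction, 4)
        self.fc1 = Conv2d(channels, hidden, 1, rng, padding=0)
        self.fc2 = Conv2d(hidden, channels, 1, rng, padding=0)

    def __call__(self, x: Tensor) -> Tensor:
        s = x.mean(axis=(2, 3), keepdims=True)
        s = self.fc2(self.fc1(s).swish()).sigmoid()
        return x * s


class InvertedResidualCell(Module):
    """MobileNetV2-style cell: 1x1 expand, depthwise 3x3, SE, 1x1 project, skip."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 expansion: int = 6, se_reduction: int = 16):
        super().__init__()
        hidden = channels * expansion
        self.expand = Conv2d(channels, hidden, 1, rng, padding=0)
        self.dw = DepthwiseConv2d(hidden, 3, rng)
        self.se = SqueezeExcite(hidden, rng, se_reduction)
        self.project = Conv2d(hidden, channels, 1, rng, padding=0)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.expand(x).swish()
        h = self.dw(h).swish()
        h = self.se(h)
        return x + self.project(h)


class ResNetBlock(Module):
    """Plain two-conv residual block used by the image decoders."""

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.c1 = Conv2d(channels, channels, 3, rng)
        self.c2 = Conv2d(channels, channels, 3, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return x + self.c2(self.c1(x).swish())


class PatchDiscriminator(Module):
    """PatchGAN: stacked stride-2 4x4 convolutions emitting a logit map.

    With the default three stride-2 stages the receptive field is the
    standard ~70x70 patch; ``n_strided`` shrinks automatically through
    the model for small image sizes so the logit map stays spatial.
    """

    def __init__(self, rng: np.random.Generator, in_channels: int = 1,
                 base: int = 64, n_strided: int = 3):
        super().__init__()
        convs = []
        cin = in_channels
        c = base
        for _ in range(n_strided):
            convs.append(Conv2d(cin, c, 4, rng, stride=2, padding=1))
            cin, c = c, min(c * 2, base * 4)
        convs.append(Conv2d(cin, c, 4, rng, stride=1, padding=1))
        self.convs = convs
        self.out = Conv2d(c, 1, 4, rng, stride=1, padding=1)

    def __call__(self, x: Tensor) -> Tensor:
        h = x
        for conv in self.convs:
            h = conv(h).leaky_relu(0.2)
        return self.out(h)


class Adam:
    """Adam optimizer over a fixed parameter list; state is checkpointable."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data = p.data - self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def state_dict(self) -> dict:
        out = {"t": np.asarray(self.t)}
        for i, (m, v) in enumerate(zip(self.m, self.v)):
            out[f"m.{i}"] = m.copy()
            out[f"v.{i}"] = v.copy()
        return out

    def load_state_dict(self, state: dict):
        self.t = int(state["t"])
        for i in range(len(self.params)):
            self.m[i] = np.asarray(state[f"m.{i}"]).copy()
            self.v[i] = np.asarray(state[f"v.{i}"]).copy()
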