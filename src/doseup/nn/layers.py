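"""Neural-network building blocks on top of the autograd engine.

Modules follow the familiar container pattern: each module owns named
parameters and submodules, ``parameters()`` walks the tree, and
``state_dict``/``load_state_dict`` serialize to flat name->ndarray maps.
Initialization is Gaussian(0, 0.02) as is conventional for image-to-image
GANs, drawn from an explicit ``numpy.random.Generator`` so builds are
bit-reproducible under a seed.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = [
    "Module",
    "Conv2d",
    "InstanceNorm2d",
    "ReLU",
    "LeakyReLU",
    "Tanh",
    "Sequential",
    "ResnetBlock",
    "Linear",
]

INIT_GAIN = 0.02


class Module:
    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, m in self._modules.items():
            out.update(m.named_parameters(prefix + name + "."))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = self.named_parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for k, v in params.items():
            v.data = np.asarray(state[k], dtype=v.data.dtype).reshape(v.data.shape).copy()

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """Convolution with explicit padding mode (zero/reflect/edge)."""

    def __init__(self, in_ch: int, out_ch: int, k: int, stride: int = 1,
                 padding: int = 0, pad_mode: str = "zero", bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.padding = padding
        self.pad_mode = pad_mode
        w = rng.normal(0.0, INIT_GAIN, size=(out_ch, in_ch, k, k)).astype(np.float32)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if self.padding:
            x = x.pad2d(self.padding, self.pad_mode)
        return x.conv2d(self.weight, self.bias, self.stride)


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalization with learned affine parameters."""

    def __init__(self, ch: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones((1, ch, 1, 1), np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros((1, ch, 1, 1), np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(2, 3), keepdims=True)
        xhat = xc / (var + self.eps).sqrt()
        return xhat * self.gamma + self.beta


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)


class Tanh(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.tanh()


class Upsample2x(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.upsample_nearest2x()


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class ResnetBlock(Module):
    """conv-norm-relu-conv-norm with a residual skip; reflect padding."""

    def __init__(self, ch: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(ch, ch, 3, padding=1, pad_mode="reflect", rng=rng)
        self.norm1 = InstanceNorm2d(ch)
        self.conv2 = Conv2d(ch, ch, 3, padding=1, pad_mode="reflect", rng=rng)
        self.norm2 = InstanceNorm2d(ch)

    def forward(self, x: Tensor) -> Tensor:
        h = self.norm1(self.conv1(x)).relu()
        h = self.norm2(self.conv2(h))
        return x + h


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator):
        super().__init__()
        w = rng.normal(0.0, INIT_GAIN, size=(in_f, out_f)).astype(np.float32)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_f, np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias
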