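"""Layer modules built on the autodiff tensor.

Modules hold named :class:`Tensor` parameters (and non-learned buffers such as
batch-norm running statistics) and expose ``named_parameters`` for the
optimizer and checkpointing.  Initialization draws from an explicit
``numpy.random.Generator`` so a run is a pure function of its seed.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor
from . import functional as F

_F32 = np.float32


class Module:
    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._children: dict[str, "Module"] = {}
        self.training = True

    # registration -----------------------------------------------------

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # traversal ---------------------------------------------------------

    def named_parameters(self, prefix: str = ""):
        for k, v in self._params.items():
            yield prefix + k, v
        for k, child in self._children.items():
            yield from child.named_parameters(prefix + k + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for k, v in self._buffers.items():
            yield prefix + k, v
        for k, child in self._children.items():
            yield from child.named_buffers(prefix + k + ".")

    def modules(self):
        yield self
        for child in self._children.values():
            yield from child.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # checkpoint --------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {k: p.data.copy() for k, p in self.named_parameters()}
        for k, b in self.named_buffers():
            out["buffer:" + k] = b.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for k, v in state.items():
            if k.startswith("buffer:"):
                name = k[len("buffer:"):]
                for bk, b in self.named_buffers():
                    if bk == name:
                        b[...] = v
                        break
                else:
                    raise KeyError(f"unknown buffer {name!r} in checkpoint")
            else:
                if k not in params:
                    raise KeyError(f"unknown parameter {k!r} in checkpoint")
                if params[k].data.shape != v.shape:
                    raise ValueError(f"shape mismatch for {k!r}")
                params[k].data[...] = v

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods):
        super().__init__()
        self.items = list(mods)
        for i, m in enumerate(self.items):
            self._children[str(i)] = m

    def __iter__(self):
        return iter(self.items)

    def __len__(self):
        return len(self.items)

    def __getitem__(self, i):
        return self.items[i]


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    std = np.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, std, size=shape).astype(_F32), requires_grad=True)


class Conv2d(Module):
    def __init__(self, rng, cin, cout, k, stride=1, bias=True, gain=1.0):
        super().__init__()
        self.stride = stride
        w = _he_init(rng, (cout, cin, k, k), cin * k * k)
        w.data *= _F32(gain)
        self.weight = w
        self.bias = Tensor(np.zeros(cout, _F32), requires_grad=True) if bias else None

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, stride=self.stride)


class DWConv(Module):
    """Depthwise conv; 3x3 taps use shifted adds, larger kernels go via FFT."""

    def __init__(self, rng, c, k, dilation=1):
        super().__init__()
        self.k, self.dilation = k, dilation
        self.weight = _he_init(rng, (c, k, k), k * k)
        self.bias = Tensor(np.zeros(c, _F32), requires_grad=True)

    def forward(self, x):
        if self.k == 3:
            return F.dwconv3x3(x, self.weight, self.bias, dilation=self.dilation)
        if self.dilation != 1:
            raise NotImplementedError("dilation only supported for 3x3 depthwise")
        return F.dwconv_fft(x, self.weight, self.bias)


class PReLU(Module):
    def __init__(self, c: int | None = None, init: float = 0.25):
        super().__init__()
        shape = (1, c, 1, 1) if c else (1,)
        self.alpha = Tensor(np.full(shape, init, _F32), requires_grad=True)

    def forward(self, x):
        return x.prelu(self.alpha)


class SEBlock(Module):
    """Squeeze-and-excitation channel gate (global pool -> bottleneck MLP -> sigmoid)."""

    def __init__(self, rng, c, reduction=8):
        super().__init__()
        mid = max(1, c // reduction)
        self.fc1 = Conv2d(rng, c, mid, 1)
        self.fc2 = Conv2d(rng, mid, c, 1)

    def forward(self, x):
        s = F.global_avg_pool(x)
        s = self.fc2(self.fc1(s).relu()).sigmoid()
        return x * s


class ChannelAffine(Module):
    """Per-channel learnable gain and bias (a 1x1 'linearization')."""

    def __init__(self, c):
        super().__init__()
        self.gain = Tensor(np.ones((1, c, 1, 1), _F32), requires_grad=True)
        self.bias = Tensor(np.zeros((1, c, 1, 1), _F32), requires_grad=True)

    def forward(self, x):
        return x * self.gain + self.bias


class LayerNormChannels(Module):
    """Normalize over the channel axis at every spatial position.

    ``init_gain`` sets the initial output scale; residual blocks use a small
    value so a freshly initialized network stays close to its skip paths."""

    def __init__(self, c, eps=1e-5, init_gain=1.0):
        super().__init__()
        self.eps = eps
        self.gain = Tensor(np.full((1, c, 1, 1), init_gain, _F32), requires_grad=True)
        self.bias = Tensor(np.zeros((1, c, 1, 1), _F32), requires_grad=True)

    def forward(self, x):
        mu = x.mean(axis=1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.gain + self.bias


class BatchNorm2d(Module):
    def __init__(self, c, eps=1e-5, momentum=0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gain = Tensor(np.ones((1, c, 1, 1), _F32), requires_grad=True)
        self.bias = Tensor(np.zeros((1, c, 1, 1), _F32), requires_grad=True)
        self.register_buffer("running_mean", np.zeros(c, _F32))
        self.register_buffer("running_var", np.ones(c, _F32))

    def forward(self, x):
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean *= 1 - m
            self.running_mean += m * mu.data.reshape(-1)
            self.running_var *= 1 - m
            self.running_var += m * var.data.reshape(-1)
            return xc / (var + self.eps).sqrt() * self.gain + self.bias
        mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
        var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        return (x - mu) / (var + self.eps).sqrt() * self.gain + self.bias


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.items = list(mods)
        for i, m in enumerate(self.items):
            self._children[str(i)] = m

    def forward(self, x):
        for m in self.items:
            x = m(x)
        return x
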