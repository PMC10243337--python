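"""Layer modules built on the autograd primitives.

Modules follow the familiar container pattern: parameters are
:class:`~lumbarseg.nn.autograd.Tensor` leaves with ``requires_grad=True``,
sub-modules are discovered from attributes, and ``state_dict`` /
``load_state_dict`` serialize flat name->array mappings.
"""

from __future__ import annotations

import numpy as np

from . import autograd as F
from .autograd import Tensor


class Module:
    """Base class: parameter registry, train/eval mode, state dicts."""

    def __init__(self) -> None:
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_parameter(self, name: str, value: Tensor) -> Tensor:
        value.requires_grad = True
        self._params[name] = value
        object.__setattr__(self, name, value)
        return value

    def register_buffer(self, name: str, value: np.ndarray) -> np.ndarray:
        self._buffers[name] = value
        object.__setattr__(self, name, value)
        return value

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + n, p) for n, p in self._params.items()]
        for mname, mod in self._modules.items():
            out.extend(mod.named_parameters(prefix + mname + "."))
        return out

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> list[tuple[str, np.ndarray]]:
        out = [(prefix + n, b) for n, b in self._buffers.items()]
        for mname, mod in self._modules.items():
            out.extend(mod.named_buffers(prefix + mname + "."))
        return out

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for mod in self._modules.values():
            mod.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {name: p.data.copy() for name, p in self.named_parameters()}
        d.update({name: b.copy() for name, b in self.named_buffers()})
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        expected = set(own) | set(bufs)
        if expected != set(d):
            missing = expected - set(d)
            extra = set(d) - expected
            raise KeyError(f"state mismatch: missing {sorted(missing)}, unexpected {sorted(extra)}")
        for name, p in own.items():
            if p.data.shape != d[name].shape:
                raise ValueError(f"{name}: shape {d[name].shape} != {p.data.shape}")
            p.data = d[name].astype(p.data.dtype).copy()
        for name, b in bufs.items():
            b[...] = d[name]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv3d(Module):
    """Stride-1 'same' 3D convolution with He-normal init.

    ``bias=False`` is used where a batch-norm follows (a bias there is
    redundant: normalization removes any constant shift).
    """

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator,
                 bias: bool = True, dtype=np.float32):
        super().__init__()
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        fan_in = in_ch * k ** 3
        std = np.sqrt(2.0 / fan_in)
        w = rng.normal(0.0, std, size=(out_ch, in_ch, k, k, k)).astype(dtype)
        self.register_parameter("weight", Tensor(w))
        self.bias = None
        if bias:
            self.register_parameter("bias", Tensor(np.zeros(out_ch, dtype=dtype)))

    def forward(self, x: Tensor) -> Tensor:
        return F.conv3d(x, self.weight, self.bias)


class ConvTranspose3d2x(Module):
    """2x2x2 stride-2 transposed convolution (learned 2x upsampling)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        std = np.sqrt(2.0 / (in_ch * 8))
        w = rng.normal(0.0, std, size=(in_ch, out_ch, 2, 2, 2)).astype(dtype)
        self.register_parameter("weight", Tensor(w))
        self.register_parameter("bias", Tensor(np.zeros(out_ch, dtype=dtype)))

    def forward(self, x: Tensor) -> Tensor:
        return F.conv_transpose3d_2x(x, self.weight, self.bias)


class BatchNorm3d(Module):
    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.register_parameter("gamma", Tensor(np.ones(n_ch, dtype=dtype)))
        self.register_parameter("beta", Tensor(np.zeros(n_ch, dtype=dtype)))
        self.register_buffer("running_mean", np.zeros(n_ch, dtype=np.float64))
        self.register_buffer("running_var", np.ones(n_ch, dtype=np.float64))

    def forward(self, x: Tensor) -> Tensor:
        return F.batchnorm(x, self.gamma, self.beta, self.running_mean,
                           self.running_var, self.training, self.momentum, self.eps)


class ConvBNReLU(Module):
    """conv -> batch-norm -> ReLU, the basic block of both networks."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.conv = Conv3d(in_ch, out_ch, k, rng, bias=False)
        self.bn = BatchNorm3d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        return F.relu(self.bn(self.conv(x)))


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)
        for i, m in enumerate(mods):
            self._modules[str(i)] = m

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class Adam:
    """Adam optimizer with the standard bias-corrected moments."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
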