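"""Neural-network building blocks on top of the autodiff engine.

Layers follow the pix2pix conventions used by the synthesis network:
4x4 convolutions, LeakyReLU encoders, batch/instance normalization
without learnable affine parameters (the parameter-count ledger puts all
learnable scalars in the convolution weights and biases).
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, conv2d, conv_transpose2d

__all__ = [
    "Module",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "InstanceNorm2d",
    "Adam",
]


class Module:
    """Base class: parameter registry, train/eval mode, state dict."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def register_parameter(self, name: str, value: np.ndarray) -> Tensor:
        p = Tensor(value, requires_grad=True)
        self._params[name] = p
        return p

    def add_module(self, name: str, module: "Module") -> "Module":
        self._modules[name] = module
        return module

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def named_buffers(self, prefix: str = ""):
        for k, v in self._buffers().items():
            yield prefix + k, v
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def state_dict(self, prefix: str = ""):
        out = {name: p.data.copy() for name, p in self.named_parameters(prefix)}
        out.update({name: np.array(v) for name, v in self.named_buffers(prefix)})
        return out

    def load_state_dict(self, state: dict, prefix: str = ""):
        for name, p in self._params.items():
            p.data = np.array(state[prefix + name], dtype=p.data.dtype)
        for k in self._buffers():
            self._set_buffer(k, np.array(state[prefix + k]))
        for name, m in self._modules.items():
            m.load_state_dict(state, prefix + name + ".")

    def _buffers(self) -> dict:
        return {}

    def _set_buffer(self, name: str, value: np.ndarray):
        raise KeyError(name)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 pad: int = 0, bias: bool = True, rng: np.random.Generator | None = None,
                 init_sd: float = 0.02, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride, self.pad = stride, pad
        w = rng.normal(0.0, init_sd, (c_out, c_in, kernel, kernel))
        self.weight = self.register_parameter("weight", w.astype(dtype))
        self.bias = (
            self.register_parameter("bias", np.zeros(c_out, dtype=dtype))
            if bias else None
        )

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.pad)


class ConvTranspose2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 pad: int = 0, bias: bool = True, rng: np.random.Generator | None = None,
                 init_sd: float = 0.02, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride, self.pad = stride, pad
        w = rng.normal(0.0, init_sd, (c_in, c_out, kernel, kernel))
        self.weight = self.register_parameter("weight", w.astype(dtype))
        self.bias = (
            self.register_parameter("bias", np.zeros(c_out, dtype=dtype))
            if bias else None
        )

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose2d(x, self.weight, self.bias, self.stride, self.pad)


class _Norm2d(Module):
    """Shared machinery for batch/instance norm (affine-free)."""

    def __init__(self, channels: int, eps: float = 1e-5):
        super().__init__()
        self.channels = channels
        self.eps = eps

    def _normalize(self, x: Tensor, axes: tuple) -> Tensor:
        mu = x.mean(axis=axes, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=axes, keepdims=True)
        return xc * ((var + self.eps) ** -0.5)


class BatchNorm2d(_Norm2d):
    """Per-channel normalization over (N, H, W).

    Batch statistics are used in training *and* at inference (the usual
    choice for image-translation GANs, where running averages collected
    under an adversarial schedule are unreliable); running statistics
    are still tracked for diagnostics and checkpointing.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__(channels, eps)
        self.momentum = momentum
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)

    def forward(self, x: Tensor) -> Tensor:
        out = self._normalize(x, (0, 2, 3))
        if self.training:
            m = x.data.mean(axis=(0, 2, 3))
            v = x.data.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (m - self.running_mean)
            self.running_var += self.momentum * (v - self.running_var)
        return out

    def _buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def _set_buffer(self, name, value):
        setattr(self, name, value.astype(np.float64))


class InstanceNorm2d(_Norm2d):
    """Per-sample, per-channel normalization over (H, W); stateless."""

    def forward(self, x: Tensor) -> Tensor:
        return self._normalize(x, (2, 3))


class Adam:
    """Adam optimizer (Kingma & Ba) with bias correction."""

    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.5,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]
        self.v = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            update = self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            p.data = (p.data.astype(np.float64) - update).astype(p.data.dtype)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
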