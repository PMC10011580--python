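"""Neural-network layers built on the autodiff engine.

Layers follow the familiar Module pattern: parameters are registered
tensors, ``train()``/``eval()`` toggles batch-norm statistics and dropout,
and ``parameters()`` walks the module tree.  Weight initialisation is
He-style fan-in scaling from a ``numpy.random.Generator`` supplied at
construction, so two builds from the same seed are bit-identical.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv3d

__all__ = ["Module", "Conv3d", "BatchNorm3d", "Dropout", "ResidualBlock"]


class Module:
    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register(self, name: str, tensor: Tensor) -> Tensor:
        tensor.requires_grad = True
        self._params[name] = tensor
        object.__setattr__(self, name, tensor)
        return tensor

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for mname, m in self._modules.items():
            yield from m.named_parameters(prefix + mname + ".")

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    # checkpoint (de)serialisation -----------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for mname, m in self._named_modules(""):
            for bname, buf in getattr(m, "_buffers", {}).items():
                state[mname + bname] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name], dtype=p.data.dtype).copy()
        for mname, m in self._named_modules(""):
            for bname in getattr(m, "_buffers", {}):
                m._buffers[bname] = np.asarray(state[mname + bname]).copy()

    def _named_modules(self, prefix: str):
        yield prefix, self
        for mname, m in self._modules.items():
            yield from m._named_modules(prefix + mname + ".")


class Conv3d(Module):
    """3D convolution with 'same' padding by default (odd kernels)."""

    def __init__(self, in_ch: int, out_ch: int, kernel, rng: np.random.Generator,
                 stride=(1, 1, 1), padding="same", bias: bool = True):
        super().__init__()
        kernel = tuple(kernel)
        self.stride = tuple(stride)
        if padding == "same":
            self.padding = tuple(k // 2 for k in kernel)
        else:
            self.padding = tuple(padding)
        fan_in = in_ch * int(np.prod(kernel))
        scale = np.sqrt(2.0 / fan_in)
        w = rng.standard_normal((out_ch, in_ch) + kernel) * scale
        self.register("weight", Tensor(w.astype(np.float32)))
        if bias:
            self.register("bias", Tensor(np.zeros(out_ch, dtype=np.float32)))
        else:
            self.bias = None

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm3d(Module):
    def __init__(self, n_ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.register("gamma", Tensor(np.ones(n_ch, dtype=np.float32)))
        self.register("beta", Tensor(np.zeros(n_ch, dtype=np.float32)))
        self._buffers = {
            "running_mean": np.zeros(n_ch, dtype=np.float32),
            "running_var": np.ones(n_ch, dtype=np.float32),
        }

    def __call__(self, x: Tensor) -> Tensor:
        C = x.shape[1]
        shape = (1, C, 1, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3, 4), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3, 4), keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] *= 1 - m
            self._buffers["running_mean"] += m * mu.data.reshape(C)
            self._buffers["running_var"] *= 1 - m
            self._buffers["running_var"] += m * var.data.reshape(C)
        else:
            mu = Tensor(self._buffers["running_mean"].reshape(shape))
            var = Tensor(self._buffers["running_var"].reshape(shape))
        xhat = (x - mu) / (var + self.eps).sqrt()
        return xhat * self.gamma.reshape(*shape) + self.beta.reshape(*shape)


class Dropout(Module):
    """Inverted dropout; ``force_active`` enables MC-dropout at inference."""

    def __init__(self, rate: float):
        super().__init__()
        self.rate = float(rate)
        self.force_active = False
        self.rng = np.random.default_rng(0)

    def __call__(self, x: Tensor) -> Tensor:
        if self.rate <= 0 or not (self.training or self.force_active):
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(x.data.dtype) / keep
        return x * Tensor(mask)


class ResidualBlock(Module):
    """Anisotropic residual block: 1x3x3 conv -> BN -> ReLU -> 3x3x3 conv -> BN,
    identity (or 1x1x1-projected) shortcut, final ReLU.

    ``isotropic=True`` replaces the 1x3x3 convolution with 3x3x3 (for 1 mm³
    inputs where no in-plane/through-plane asymmetry is wanted).
    """

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 isotropic: bool = False):
        super().__init__()
        k1 = (3, 3, 3) if isotropic else (1, 3, 3)
        self.conv1 = Conv3d(in_ch, out_ch, k1, rng)
        self.bn1 = BatchNorm3d(out_ch)
        self.conv2 = Conv3d(out_ch, out_ch, (3, 3, 3), rng)
        self.bn2 = BatchNorm3d(out_ch)
        if in_ch != out_ch:
            self.proj = Conv3d(in_ch, out_ch, (1, 1, 1), rng)
        else:
            self.proj = None

    def __call__(self, x: Tensor) -> Tensor:
        h = self.bn1(self.conv1(x)).relu()
        h = self.bn2(self.conv2(h))
        shortcut = x if self.proj is None else self.proj(x)
        return (h + shortcut).relu()
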